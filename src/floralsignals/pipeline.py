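"""End-to-end orchestration of the colour, shape and trait-mapping analyses.

A run is driven by a :class:`RunConfig` (typically read from YAML); every
stochastic stage derives its randomness from the single mandatory seed, the
config is echoed verbatim into the output directory, and all outputs are
plain text (CSV / newick / JSON) written deterministically so that two runs
with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from floralsignals import bee_vision, community_stats, eigenshape, spectra_io, synthetic_data, trait_mapping

log = logging.getLogger("floralsignals")


class PipelineConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All inputs and constants of a full analysis run, in one visible place."""

    seed: int
    # colour stage
    spectra: str | None = None  # CSV path; None -> default synthetic community
    receptors: list | None = None  # three sensitivity CSVs (UV, blue, green)
    illuminant: str | None = None
    background: str | None = None
    grid: tuple = (300.0, 700.0, 1.0)
    n_boot: int = 1000
    focal_species: list = field(default_factory=list)  # [] -> all UV-green species
    achromatic_radius: float = bee_vision.DEFAULT_ACHROMATIC_RADIUS
    # shape stage
    outlines: str | None = None  # coordinate CSV; None -> synthetic two-group set
    outline_metadata: str | None = None
    m: int = 100
    retain_fraction: float = 0.90
    cva_validation: str = "resubstitution"
    target_family: str = "synthetic"
    exclude_specimens: list = field(default_factory=list)
    # trait stage
    tree: str | None = None  # newick path; None -> synthetic planted-gain tree
    states: str | None = None  # TSV path
    n_tips: int = 200
    planted_gains: int = 14
    # diagnostics
    plots: bool = False  # write loci / score-space scatter PNGs per stage

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise PipelineConfigError("config field 'seed' is mandatory")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.grid = tuple(cfg.grid)
        return cfg

    def echo(self, outdir: Path) -> None:
        d = asdict(self)
        d["grid"] = list(self.grid)
        (outdir / "config_echo.yaml").write_text(yaml.safe_dump(d, sort_keys=True))


def _outdir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


def run_colour_analysis(cfg: RunConfig, outdir) -> dict:
    """Loci, sector table, per-focal distinctness tests and UV-green group contrast."""
    out = _outdir(outdir)
    if cfg.spectra is None:
        sset, truth = synthetic_data.gen_community(seed=cfg.seed)
        truth.to_csv(out / "community_truth.csv", index=False)
    else:
        if not Path(cfg.spectra).exists():
            raise PipelineConfigError(f"config field 'spectra': file not found: {cfg.spectra}")
        sset = spectra_io.read_spectra(cfg.spectra)
    sset = spectra_io.SpectrumSet(
        spectra=[spectra_io.resample(s, cfg.grid) for s in sset],
        site=sset.site,
        habitat=sset.habitat,
    )
    sset = spectra_io.aggregate_replicates(sset)
    log.info("colour: %d aggregated spectra", len(sset))

    receptors = (
        bee_vision.ReceptorSet.from_csvs(cfg.receptors, cfg.grid) if cfg.receptors else None
    )
    if cfg.background is not None and not Path(cfg.background).exists():
        raise PipelineConfigError(f"config field 'background': file not found: {cfg.background}")
    if cfg.illuminant is not None and not Path(cfg.illuminant).exists():
        raise PipelineConfigError(f"config field 'illuminant': file not found: {cfg.illuminant}")
    model = bee_vision.HexagonVisionModel(
        receptors=receptors, illuminant=cfg.illuminant, background=cfg.background, grid=cfg.grid
    ).fit()
    loci = model.loci(sset).sort_values("species", ignore_index=True)
    loci.to_csv(out / "loci.csv", index=False)
    if cfg.plots:
        from floralsignals import plots

        plots.plot_hexagon_loci(loci, out / "loci_hexagon.png", cfg.achromatic_radius)

    focals = cfg.focal_species or list(loci.loc[loci["sector"] == "UV-green", "species"])
    rows = []
    for i, focal in enumerate(sorted(focals)):
        res = community_stats.focal_distinctness_test(
            loci, focal, n_boot=cfg.n_boot, seed=cfg.seed + 1 + i
        )
        rows.append(asdict(res) if hasattr(res, "__dataclass_fields__") else vars(res))
    focal_df = pd.DataFrame(rows)
    focal_df.to_csv(out / "focal_tests.csv", index=False)
    log.info("colour: %d focal tests (n_boot=%d)", len(rows), cfg.n_boot)

    section: dict = {"n_species": int(len(loci)), "focal_tests": rows}
    try:
        gc = community_stats.uvgreen_group_test(loci)
        pd.DataFrame([vars(gc)]).to_csv(out / "group_contrast.csv", index=False)
        section["group_contrast"] = vars(gc)
    except community_stats.CommunitySizeError as exc:
        log.info("colour: group contrast skipped (%s)", exc)
        section["group_contrast"] = None
    return section


def run_shape_analysis(cfg: RunConfig, outdir) -> dict:
    """Eigenshape decomposition, axis retention, nearest-model test, CVA rate."""
    out = _outdir(outdir)
    if cfg.outlines is None:
        outlines = synthetic_data.gen_outlines(seed=cfg.seed)
    else:
        if not Path(cfg.outlines).exists():
            raise PipelineConfigError(f"config field 'outlines': file not found: {cfg.outlines}")
        outlines = eigenshape.read_outlines_csv(cfg.outlines, cfg.outline_metadata)
    phi, meta = eigenshape.outlines_to_phi_matrix(outlines, m=cfg.m)
    full = eigenshape.eigenshape_decompose(phi, metadata=meta)
    kept = eigenshape.retain_axes(full, cfg.retain_fraction)
    log.info("shape: %d specimens, %d/%d axes at %.0f%% variance",
             phi.shape[0], kept.n_axes, full.n_axes, 100 * cfg.retain_fraction)

    scores = pd.concat(
        [meta, pd.DataFrame(kept.scores, columns=[f"axis_{i+1}" for i in range(kept.n_axes)])],
        axis=1,
    )
    scores.to_csv(out / "eigen_scores.csv", index=False)
    if cfg.plots and kept.n_axes >= 2:
        from floralsignals import plots

        plots.plot_score_space(scores, out / "score_space.png")
    pd.DataFrame(
        {
            "axis": np.arange(1, full.n_axes + 1),
            "eigenvalue": full.eigenvalues,
            "variance_fraction": full.variance_fraction,
        }
    ).to_csv(out / "eigen_values.csv", index=False)

    section: dict = {
        "n_specimens": int(phi.shape[0]),
        "n_axes_total": int(full.n_axes),
        "n_axes_retained": int(kept.n_axes),
        "retain_fraction": cfg.retain_fraction,
    }
    fam = meta["family"].to_numpy()
    if (fam == cfg.target_family).any() and not (fam == cfg.target_family).all():
        dist = eigenshape.nearest_group_distance(kept.scores, fam, cfg.target_family)
        groups = meta["group"].to_numpy()
        try:
            gt = eigenshape.group_distance_test(
                dist,
                groups,
                mimic_group=sorted(set(groups))[0],
                other_group=sorted(set(groups))[1],
                exclude=cfg.exclude_specimens or None,
                labels=meta["specimen_id"],
            )
            section["nearest_model_test"] = vars(gt)
        except ValueError as exc:
            log.info("shape: nearest-model test skipped (%s)", exc)
            section["nearest_model_test"] = None
    else:
        section["nearest_model_test"] = None

    cva = eigenshape.cva_two_group(kept.scores, meta["group"], validation=cfg.cva_validation)
    loo = eigenshape.cva_two_group(kept.scores, meta["group"], validation="leave-one-out")
    pd.DataFrame(
        [
            {
                "validation": r.validation,
                "classification_rate": r.classification_rate,
                "n": r.n,
                "regularized": r.regularized,
                "confusion": json.dumps(r.confusion.tolist()),
            }
            for r in (cva, loo)
        ]
    ).to_csv(out / "cva_report.csv", index=False)
    section["cva_rate"] = cva.classification_rate
    section["cva_rate_loo"] = loo.classification_rate
    return section


def run_trait_mapping(cfg: RunConfig, outdir) -> dict:
    """Parsimony score, origin bracket, genus summary and annotated newick."""
    out = _outdir(outdir)
    if cfg.tree is None or cfg.states is None:
        tree, char, truth = synthetic_data.gen_tree_with_character(
            n_tips=cfg.n_tips, planted_gains=cfg.planted_gains, seed=cfg.seed
        )
        genus_map = {tip: f"clade{i+1:02d}" for i, tips in enumerate(truth.clade_tip_sets) for tip in tips}
    else:
        tree = trait_mapping.read_newick(cfg.tree)
        char, genus_map = trait_mapping.read_character_tsv(cfg.states)
        truth = None
    result = trait_mapping.fitch_parsimony(tree, char)
    annotated = trait_mapping.annotate_tree(tree, char)
    (out / "annotated_tree.nwk").write_text(annotated + "\n")
    genus = trait_mapping.genus_origin_summary(char, genus_map)
    genus.to_csv(out / "genus_summary.csv", index=False)
    section = {
        "n_tips": sum(1 for _ in tree.leaf_node_iter()),
        "parsimony_score": result.parsimony_score,
        "min_gains": result.min_gains,
        "max_gains": result.max_gains,
        "root_states": list(result.root_states),
        "n_genera_with_state": int(genus["has_state"].sum()),
    }
    if truth is not None:
        section["true_gains"] = truth.n_gains
    (out / "origins.json").write_text(json.dumps(section, indent=2, sort_keys=True) + "\n")
    log.info("trait: score=%d gains=[%d, %d]", result.parsimony_score,
             result.min_gains, result.max_gains)
    return section


def run_all(cfg: RunConfig, outdir) -> dict:
    """Run every stage; write the combined report and echo the config."""
    out = _outdir(outdir)
    cfg.echo(out)
    report = {
        "colour": run_colour_analysis(cfg, out / "colour"),
        "shape": run_shape_analysis(cfg, out / "shape"),
        "trait": run_trait_mapping(cfg, out / "trait"),
        "seed": cfg.seed,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    lines = ["floralsignals run report", "========================", ""]
    c = report["colour"]
    lines.append(f"colour: {c['n_species']} species; {len(c['focal_tests'])} focal tests")
    for ft in c["focal_tests"]:
        lines.append(f"  focal {ft['focal']}: T={ft['T']:.4f} hexagon units, p={ft['p']:.4f}")
    if c["group_contrast"]:
        g = c["group_contrast"]
        lines.append(f"  UV-green contrast: t={g['t']:.3f}, df={g['df']:.2f}, p={g['p']:.2e}")
    s = report["shape"]
    lines.append(
        f"shape: {s['n_specimens']} specimens; {s['n_axes_retained']} axes at "
        f"{100*s['retain_fraction']:.0f}% variance; CVA rate {s['cva_rate']:.3f} "
        f"(LOO {s['cva_rate_loo']:.3f})"
    )
    t = report["trait"]
    lines.append(
        f"trait: {t['n_tips']} tips; parsimony score {t['parsimony_score']}; "
        f"origins in [{t['min_gains']}, {t['max_gains']}]; "
        f"{t['n_genera_with_state']} genera with the state"
    )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report
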