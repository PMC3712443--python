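"""Synthetic spectra, floral outlines, and trees with known ground truth.

Every analysis stage in this package can be exercised without field data:

* parametric reflectance templates for the main floral colour classes — in
  particular the "yellow" class that combines long-wavelength (human-yellow)
  reflectance with a UV bump, the combination that lands in the bee-UV-green
  sector of the colour hexagon — plus a green-foliage background;
* two-group open-curve outlines built from a half-period sine basis (anchors
  fixed at the curve ends) with per-specimen Gaussian harmonic noise;
* pure-birth trees carrying a binary character either with a known number of
  planted, irreversible gains on disjoint clades, or evolved under a two-state
  Markov gain/loss process.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from floralsignals.bee_vision import default_background
from floralsignals.eigenshape import Outline
from floralsignals.spectra_io import DEFAULT_GRID, ReflectanceSpectrum, SpectrumSet, make_grid


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# spectra

#: Template parameters per colour class. ``longpass`` = (inflection nm, slope
#: nm, amplitude); ``uv_bump`` = (centre nm, sd nm, height); ``gaussian`` =
#: (centre nm, sd nm, height); ``base`` = wavelength-independent floor.
SPECTRUM_CLASSES = {
    "bee-uv-green-yellow": {"longpass": (520.0, 15.0, 0.80), "uv_bump": (360.0, 25.0, 0.35), "base": 0.02},
    "blue": {"gaussian": (460.0, 35.0, 0.65), "base": 0.01},
    "white": {"longpass": (390.0, 12.0, 0.80), "base": 0.02},
    "cream": {"longpass": (420.0, 25.0, 0.55), "base": 0.04},
    "red-human": {"longpass": (610.0, 12.0, 0.70), "base": 0.02},
    "leaf-background": {},
}

#: Default community composition: a small bee-UV-green group (emulating the
#: mimic orchids together with their rewarding models), with blue-green-ish
#: (white/cream) flowers the commonest class, as in the field communities
#: this emulates.
DEFAULT_COMMUNITY = {
    "bee-uv-green-yellow": 4,
    "blue": 3,
    "white": 6,
    "cream": 4,
    "red-human": 3,
}


def gen_spectrum(
    spectrum_class: str,
    seed: int | None = None,
    noise_sd: float = 0.0,
    species: str = "",
    patch: str = "labellum",
    replicate_id: str = "1",
    grid=DEFAULT_GRID,
    **overrides,
) -> ReflectanceSpectrum:
    """One reflectance spectrum of a named colour class, plus Gaussian noise.

    Template parameters may be overridden by keyword (``longpass``,
    ``uv_bump``, ``gaussian``, ``base``); output is clipped to [0, 1].
    """
    if spectrum_class not in SPECTRUM_CLASSES:
        raise ConfigError(
            f"unknown spectrum class {spectrum_class!r}; choose from {sorted(SPECTRUM_CLASSES)}"
        )
    wl = make_grid(grid)
    params = dict(SPECTRUM_CLASSES[spectrum_class])
    params.update(overrides)
    if spectrum_class == "leaf-background":
        refl = default_background(grid).copy()
    else:
        refl = np.full_like(wl, params.get("base", 0.0))
        if "longpass" in params:
            lam0, slope, amp = params["longpass"]
            refl = refl + amp / (1.0 + np.exp(-(wl - lam0) / slope))
        if "gaussian" in params:
            c, sd, h = params["gaussian"]
            refl = refl + h * np.exp(-0.5 * ((wl - c) / sd) ** 2)
        if "uv_bump" in params:
            c, sd, h = params["uv_bump"]
            refl = refl + h * np.exp(-0.5 * ((wl - c) / sd) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        refl = refl + rng.normal(0.0, noise_sd, size=refl.shape)
    refl = np.clip(refl, 0.0, 1.0)
    return ReflectanceSpectrum(
        wavelengths=wl,
        reflectance=refl,
        species=species or spectrum_class,
        patch=patch,
        replicate_id=replicate_id,
    )


def gen_community(
    n: dict | None = None,
    seed: int = 0,
    noise_sd: float = 0.01,
    grid=DEFAULT_GRID,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """A labelled community of flower spectra plus its ground-truth class table.

    ``n`` maps colour class to species count (default
    :data:`DEFAULT_COMMUNITY`). Returns (SpectrumSet, truth DataFrame with
    columns species, spectrum_class).
    """
    n = dict(DEFAULT_COMMUNITY) if n is None else n
    if sum(n.values()) < 1:
        raise ConfigError("community must contain at least one species")
    rng = np.random.default_rng(seed)
    spectra, truth = [], []
    for cls in sorted(n):
        for i in range(n[cls]):
            name = f"{cls.replace('-', '_')}_{i + 1:02d}"
            sub = int(rng.integers(0, 2**31 - 1))
            spectra.append(
                gen_spectrum(cls, seed=sub, noise_sd=noise_sd, species=name, grid=grid)
            )
            truth.append({"species": name, "spectrum_class": cls})
    return SpectrumSet(spectra=spectra, site="synthetic", habitat="synthetic"), pd.DataFrame(truth)


def gen_loci_community(
    n: int = 20,
    radius: float = 0.1,
    focal_shift: float = 0.0,
    seed: int = 0,
    center: tuple[float, float] = (0.25, 0.15),
) -> pd.DataFrame:
    """Colour loci i.i.d. uniform in a disc, with the focal species shifted.

    A direct generator of hexagon coordinates (species, x, y) for calibrating
    the community distinctness bootstrap: species "focal" is displaced
    ``focal_shift`` hexagon units radially outward from the disc centre.
    """
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    x = center[0] + r * np.cos(th)
    y = center[1] + r * np.sin(th)
    species = [f"sp_{i + 1:02d}" for i in range(n - 1)] + ["focal"]
    x[-1] += focal_shift
    return pd.DataFrame({"species": species, "x": x, "y": y})


# ---------------------------------------------------------------------------
# outlines

#: Half-period sine coefficients of the default group mean shapes. The two
#: groups share the first harmonic (overall arching) and differ in the second
#: and third (lobedness), the kind of difference a labellum/corolla contrast
#: shows.
DEFAULT_OUTLINE_GROUPS = {
    "yellow": np.array([0.30, 0.12, 0.02, 0.01, 0.0, 0.0]),
    "non-yellow": np.array([0.30, -0.12, 0.05, 0.0, 0.01, 0.0]),
}


def gen_outlines(
    models: dict | None = None,
    n_per_group: int = 15,
    m: int = 100,
    within_sd: float = 0.02,
    seed: int = 0,
) -> list[Outline]:
    """Open-curve outlines for each group from mean harmonics + Gaussian noise.

    Each outline runs from (0, 0) to (1, 0) with perpendicular displacement
    ``sum_k a_k sin(k pi t)``; the half-period sine basis keeps the anchor
    landmarks exactly fixed at the curve ends. Per-specimen coefficients are
    the group mean plus N(0, within_sd) noise.
    """
    if n_per_group < 2:
        raise ConfigError("need n >= 2 outlines per group")
    models = DEFAULT_OUTLINE_GROUPS if models is None else models
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, m)
    basis = np.vstack([np.sin((k + 1) * np.pi * t) for k in range(max(len(np.atleast_1d(v)) for v in models.values()))])
    outlines = []
    for group in sorted(models):
        mean = np.atleast_1d(np.asarray(models[group], dtype=float))
        for i in range(n_per_group):
            coeffs = mean + rng.normal(0.0, within_sd, size=mean.shape)
            y = coeffs @ basis[: len(coeffs)]
            pts = np.column_stack([t, y])
            outlines.append(
                Outline(
                    points=pts,
                    species=f"{group}_sp{i + 1:02d}",
                    group=group,
                    family="synthetic",
                    specimen_id=f"{group}_{i + 1:03d}",
                )
            )
    return outlines


# ---------------------------------------------------------------------------
# trees + characters

@dataclass
class TreeCharacterTruth:
    """Ground truth accompanying a simulated (tree, character) pair."""

    mode: str  # "planted" or "rates"
    n_gains: int  # planted clade count, or realised 0->1 edge changes
    clade_tip_sets: list  # planted mode: tips of each gained clade
    seed: int


def _grow_yule_tree(n_tips: int, rng) -> dendropy.Tree:
    """Pure-birth tree: split a uniformly chosen tip until n_tips leaves."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.add_child(dendropy.Node(edge_length=float(rng.exponential(1.0))))
    tree.seed_node.add_child(dendropy.Node(edge_length=float(rng.exponential(1.0))))
    leaves = list(tree.seed_node.child_nodes())
    while len(leaves) < n_tips:
        i = int(rng.integers(0, len(leaves)))
        node = leaves.pop(i)
        for _ in range(2):
            child = dendropy.Node(edge_length=float(rng.exponential(1.0)))
            node.add_child(child)
            leaves.append(child)
    for j, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"t{j + 1:03d}")
    return tree


def _zero_pendants_between(u, v, one_tips: set) -> int:
    """Off-path child subtrees with no state-1 tips, on the path between clades u, v."""

    def tipset(node):
        return {l.taxon.label for l in node.leaf_iter()}

    ancestors_u = []
    node = u.parent_node
    while node is not None:
        ancestors_u.append(node)
        node = node.parent_node
    anc_u_set = set(id(a) for a in ancestors_u)
    path_v = []
    node = v.parent_node
    while node is not None and id(node) not in anc_u_set:
        path_v.append(node)
        node = node.parent_node
    mrca = node
    path_u = []
    node = u.parent_node
    while node is not mrca:
        path_u.append(node)
        node = node.parent_node
    count = 0
    on_path = {id(u), id(v), id(mrca)} | {id(p) for p in path_u} | {id(p) for p in path_v}
    for p in path_u + path_v + [mrca]:
        for child in p.child_nodes():
            if id(child) in on_path:
                continue
            if child in (u, v):
                continue
            if not (tipset(child) & one_tips):
                count += 1
    return count


def gen_tree_with_character(
    n_tips: int = 200,
    planted_gains: int | None = 14,
    gain_rate: float | None = None,
    loss_rate: float | None = None,
    max_clade_frac: float = 0.08,
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[dendropy.Tree, dict, TreeCharacterTruth]:
    """A pure-birth tree with a binary character of known history.

    Planted mode (default): ``planted_gains`` disjoint clades are switched to
    state 1, all other tips stay 0. Clades are chosen so that any two planted
    clade roots have at least two all-zero subtrees hanging off the path
    between them; on a binary tree this guarantees that merging gains into a
    deeper single gain plus losses is strictly more expensive, so every
    most-parsimonious reconstruction has exactly the planted number of
    origins.

    Rate mode (``gain_rate``/``loss_rate`` given, ``planted_gains=None``): a
    two-state Markov process runs root-to-tip along branch lengths; the truth
    records the realised number of 0->1 edge changes (parsimony may legally
    infer fewer when homoplasy allows).
    """
    if n_tips < 4:
        raise ConfigError("need at least 4 tips")
    rng = np.random.default_rng(seed)
    if planted_gains is not None:
        for _ in range(max_tries):
            tree = _grow_yule_tree(n_tips, rng)
            char, clades = _plant_gains(tree, planted_gains, max_clade_frac, rng)
            if char is not None:
                truth = TreeCharacterTruth(
                    mode="planted", n_gains=planted_gains, clade_tip_sets=clades, seed=seed
                )
                return tree, char, truth
        raise ConfigError(
            f"could not plant {planted_gains} separated gains on a {n_tips}-tip tree"
        )
    if gain_rate is None or loss_rate is None:
        raise ConfigError("give planted_gains, or both gain_rate and loss_rate")
    tree = _grow_yule_tree(n_tips, rng)
    char, n_gain_edges = _evolve_rates(tree, gain_rate, loss_rate, rng)
    truth = TreeCharacterTruth(mode="rates", n_gains=n_gain_edges, clade_tip_sets=[], seed=seed)
    return tree, char, truth


def _plant_gains(tree, g: int, max_clade_frac: float, rng):
    if g == 0:
        return {l.taxon.label: 0 for l in tree.leaf_node_iter()}, []
    nodes = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    max_size = max(1, int(np.ceil(max_clade_frac * len(tree.leaf_nodes()))))
    sizes = {id(n): len(n.leaf_nodes()) for n in nodes}
    candidates = [n for n in nodes if sizes[id(n)] <= max_size]
    order = rng.permutation(len(candidates))
    chosen: list = []

    def disjoint(a, b):
        n = a
        while n is not None:
            if n is b:
                return False
            n = n.parent_node
        n = b
        while n is not None:
            if n is a:
                return False
            n = n.parent_node
        return True

    for idx in order:
        cand = candidates[idx]
        if all(disjoint(cand, c) for c in chosen):
            chosen.append(cand)
            if len(chosen) == g:
                break
    if len(chosen) < g:
        return None, None
    one_tips = set()
    clade_sets = []
    for c in chosen:
        tips = {l.taxon.label for l in c.leaf_iter()}
        clade_sets.append(sorted(tips))
        one_tips |= tips
    for i in range(g):
        for j in range(i + 1, g):
            if _zero_pendants_between(chosen[i], chosen[j], one_tips) < 2:
                return None, None
    char = {l.taxon.label: (1 if l.taxon.label in one_tips else 0) for l in tree.leaf_node_iter()}
    return char, clade_sets


def _evolve_rates(tree, gain_rate: float, loss_rate: float, rng):
    states = {tree.seed_node: 0}
    n_gain_edges = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        s = states[node.parent_node]
        t = node.edge_length or 1.0
        # 2-state CTMC transition probability
        total = gain_rate + loss_rate
        if total <= 0:
            raise ConfigError("rates must be positive in rate mode")
        p_eq1 = gain_rate / total
        decay = np.exp(-total * t)
        p1 = p_eq1 + ((1.0 - p_eq1) if s == 1 else -p_eq1) * decay
        new = 1 if rng.uniform() < p1 else 0
        if s == 0 and new == 1:
            n_gain_edges += 1
        states[node] = new
    char = {l.taxon.label: states[l] for l in tree.leaf_node_iter()}
    return char, n_gain_edges
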