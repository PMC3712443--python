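"""Community-level colour statistics in hexagon space.

Two tests on a community of species colour loci (one locus per species-patch):

* a per-focal-species *distinctness* bootstrap — is a putative mimic's median
  distance to the rest of the community larger than the typical pairwise
  distance within it? — and
* a *UV-green group contrast* — are pairwise distances among species in the
  bee-UV-green sector smaller than among species elsewhere in the hexagon?

Both operate on distances only, so they are invariant to rigid motion of the
loci. The distinctness test builds its null by reassigning the focal role
uniformly among the other community members (a permutation construction,
exactly calibrated under exchangeability); a variant that additionally
resamples the non-focal set with replacement is available. The group
contrast is a one-sided
Welch two-sample t-test on pairwise distances; note pairwise distances are not
independent observations, so the t-test is a descriptive convention and the
caveat is recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


class CommunitySizeError(ValueError):
    """Too few species for the requested test."""


@dataclass(frozen=True)
class DistinctnessResult:
    """Observed statistic and bootstrap p-value for one focal species.

    T = median focal-to-other distance minus median other pairwise distance,
    in hexagon units; p is the one-sided fraction of null replicates with
    T* >= T (focal farther than typical).
    """

    focal: str
    T: float
    p: float
    n_boot: int
    seed: int
    n_species: int
    scheme: str = "permute"


@dataclass(frozen=True)
class GroupContrastResult:
    t: float
    df: float
    p: float
    n_a: int
    n_b: int
    alternative: str = "less"
    note: str = "pairwise distances are not independent; t-test is descriptive"


def _coords(loci) -> tuple[np.ndarray, list[str]]:
    """Accept a loci DataFrame (species, x, y) or a sequence of ColorLocus."""
    if isinstance(loci, pd.DataFrame):
        return loci[["x", "y"]].to_numpy(float), list(loci["species"].astype(str))
    xy = np.array([[l.x, l.y] for l in loci], dtype=float)
    return xy, [l.species for l in loci]


def _t_statistic(D: np.ndarray, focal_idx: int) -> float:
    n = D.shape[0]
    others = np.delete(np.arange(n), focal_idx)
    focal_d = D[focal_idx, others]
    iu = np.triu_indices(len(others), k=1)
    other_d = D[np.ix_(others, others)][iu]
    return float(np.median(focal_d) - np.median(other_d))


def focal_distinctness_test(
    loci,
    focal: str,
    n_boot: int = 1000,
    seed: int | None = None,
    scheme: str = "permute",
) -> DistinctnessResult:
    """Bootstrap test of whether a focal species occupies a distinct colour locus.

    Parameters
    ----------
    loci : DataFrame with columns (species, x, y), or sequence of ColorLocus
        One locus per species; >=4 species required.
    focal : str
        Species label of the putative mimic.
    n_boot : int
        Number of null replicates.
    seed : int
        Mandatory RNG seed (reproducible bit-for-bit).
    scheme : {"permute", "reassign-resample"}
        Null-generation scheme. The default ("permute") reassigns the focal
        role to a species drawn uniformly among the *other* community members,
        leaving the loci untouched — the classical permutation construction,
        exactly calibrated under exchangeability. "reassign-resample"
        additionally resamples the non-focal set with replacement to its
        original size (duplicated members' identically-zero self distances are
        excluded from the pairwise median); the extra resampling variance makes
        it mildly conservative, and it is kept for sensitivity analysis.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")
    xy, species = _coords(loci)
    n = len(species)
    if n < 4:
        raise CommunitySizeError(f"community of {n} species; need >= 4")
    if focal not in species:
        raise KeyError(f"focal species {focal!r} not in community")
    if scheme not in ("reassign-resample", "permute"):
        raise ValueError(f"unknown scheme {scheme!r}")
    focal_idx = species.index(focal)
    D = squareform(pdist(xy))
    T_obs = _t_statistic(D, focal_idx)

    rng = np.random.default_rng(seed)
    m = n - 1
    iu = np.triu_indices(m, k=1)
    candidates = np.delete(np.arange(n), focal_idx)
    focal_stars = candidates[rng.integers(0, n - 1, size=n_boot)]
    T_null = np.empty(n_boot)
    for b in range(n_boot):
        f = focal_stars[b]
        pool = np.delete(np.arange(n), f)
        if scheme == "reassign-resample":
            drawn = rng.choice(pool, size=m, replace=True)
            pair_d = D[drawn[iu[0]], drawn[iu[1]]]
            # duplicated members contribute identically-zero self distances;
            # only distances between distinct species enter the median
            pair_d = pair_d[drawn[iu[0]] != drawn[iu[1]]]
        else:
            drawn = pool
            pair_d = D[drawn[iu[0]], drawn[iu[1]]]
        other_med = np.median(pair_d) if pair_d.size else 0.0
        T_null[b] = np.median(D[f, drawn]) - other_med
    p = float(np.mean(T_null >= T_obs))
    return DistinctnessResult(
        focal=focal, T=T_obs, p=p, n_boot=n_boot, seed=seed, n_species=n, scheme=scheme
    )


def uvgreen_group_test(loci, sectors=None, group_sector: str = "UV-green") -> GroupContrastResult:
    """One-sided Welch test: are UV-green species mutually closer than others?

    Sample A holds all pairwise hexagon distances among species classified in
    the UV-green sector, sample B all pairwise distances among the remaining
    species; the alternative is mean(A) < mean(B).

    ``sectors`` maps species label -> sector name; if None and ``loci`` is a
    DataFrame with a ``sector`` column, that column is used.
    """
    xy, species = _coords(loci)
    if sectors is None:
        if isinstance(loci, pd.DataFrame) and "sector" in loci.columns:
            sectors = dict(zip(loci["species"].astype(str), loci["sector"]))
        else:
            raise ValueError("sectors mapping required")
    in_group = np.array([sectors[s] == group_sector for s in species])
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise CommunitySizeError(
            f"need >=2 species inside and outside {group_sector!r} "
            f"(got {int(in_group.sum())} / {int((~in_group).sum())})"
        )
    a = pdist(xy[in_group])
    b = pdist(xy[~in_group])
    res = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return GroupContrastResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
    )
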