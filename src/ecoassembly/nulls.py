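"""Null models: SES.beta-MNTD via tip-label shuffling and the Raup-Crick
Bray-Curtis metric (RCbray), plus the five-way pairwise process
classification.

Both nulls draw from the *regional pool* -- every taxon in the aligned
dataset.  The tip-shuffle null randomly permutes taxon identities on the
patristic distance matrix while abundances stay fixed; the Raup-Crick null
reassembles each site with its observed richness and total abundance, taxa
drawn with probability proportional to occupancy (number of sites
occupied) and individuals allocated proportionally to pooled abundance.

All randomness is driven by explicit integer seeds.  Permutations and the
per-pair Raup-Crick streams are keyed so that a removal analysis replays
the identical randomizations (see :mod:`ecoassembly.removal`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import beta_mntd, bray_curtis

__all__ = [
    "NullConfig",
    "PROCESSES",
    "tip_permutations",
    "null_beta_mntd",
    "ses_beta_mntd",
    "rc_bray",
    "classify_pair",
]

#: The five assembly processes, in reporting order.
PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

# Sub-stream tags: keep every derived seed entry below 2**31.
_TAG_TIPSHUFFLE = 11
_TAG_RAUPCRICK = 23

#: Null standard deviations at or below this are treated as degenerate.
DEGENERATE_SD = 1e-12


@dataclass
class NullConfig:
    """Randomization settings and significance thresholds.

    Attributes
    ----------
    n_reps :
        Number of randomizations (default 500; 999 is also common).
    seed :
        Base seed for every permutation stream.
    ses_cut :
        |SES.beta-MNTD| beyond this signals selection (default 2).
    rc_cut :
        |RCbray| beyond this signals a dispersal process (default 0.95).
    rule_labels :
        ``"consistent"`` labels RC > rc_cut as dispersal limitation in the
        removal decision rules, matching the two-step classification;
        ``"paper-literal"`` swaps the two dispersal labels in the removal
        rules (see docs/methods.md).
    """

    n_reps: int = 500
    seed: int = 0
    ses_cut: float = 2.0
    rc_cut: float = 0.95
    rule_labels: str = "consistent"

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be at least 2 (a null sd must exist)")
        if self.ses_cut <= 0 or self.rc_cut <= 0:
            raise ValueError("significance thresholds must be positive")
        if self.rule_labels not in ("consistent", "paper-literal"):
            raise ValueError("rule_labels must be 'consistent' or 'paper-literal'")


def tip_permutations(n_taxa: int, n_reps: int, seed: int) -> np.ndarray:
    """The shared (n_reps, n_taxa) array of tip-label permutations.

    Row r maps pool position i to shuffled position ``perm[r, i]``; the
    same array is replayed by every removal run with the same seed.
    """
    rng = np.random.default_rng([int(seed), _TAG_TIPSHUFFLE])
    return np.array([rng.permutation(n_taxa) for _ in range(n_reps)], dtype=np.intp)


def null_beta_mntd(
    D: np.ndarray,
    perms: np.ndarray,
    idx_k: np.ndarray,
    idx_m: np.ndarray,
    w_k: np.ndarray,
    w_m: np.ndarray,
    chunk: int = 128,
) -> np.ndarray:
    """Null beta-MNTD ensemble for one site pair under tip shuffling.

    ``idx_k``/``idx_m`` are pool positions of the taxa present in each
    site; ``w_k``/``w_m`` the matching relative abundances.  Each replicate
    relocates every pool position according to one permutation row and
    re-reads the patristic distances.
    """
    n_reps = perms.shape[0]
    out = np.empty(n_reps, dtype=float)
    for start in range(0, n_reps, chunk):
        P = perms[start : start + chunk]
        pk = P[:, idx_k]  # (c, a)
        pm = P[:, idx_m]  # (c, b)
        sub = D[pk[:, :, None], pm[:, None, :]]  # (c, a, b)
        out[start : start + chunk] = 0.5 * (
            sub.min(axis=2) @ w_k + sub.min(axis=1) @ w_m
        )
    return out


def ses_beta_mntd(
    D: np.ndarray,
    perms: np.ndarray,
    counts_k: np.ndarray,
    counts_m: np.ndarray,
) -> tuple[float, float, float, float]:
    """Observed beta-MNTD, null mean/sd, and the standardized effect size.

    SES = (observed - null mean) / null sd.  A vanishing null sd (e.g. a
    star tree, where every permutation returns the same value) yields
    ``ses = nan`` and must be flagged degenerate by the caller.
    """
    obs = beta_mntd(counts_k, counts_m, D)
    idx_k = np.flatnonzero(counts_k > 0)
    idx_m = np.flatnonzero(counts_m > 0)
    w_k = counts_k[idx_k] / counts_k[idx_k].sum()
    w_m = counts_m[idx_m] / counts_m[idx_m].sum()
    null = null_beta_mntd(D, perms, idx_k, idx_m, w_k, w_m)
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    ses = (obs - mean) / sd if sd > DEGENERATE_SD else float("nan")
    return obs, mean, sd, ses


def _pair_rng(seed: int, i: int, j: int) -> np.random.Generator:
    a, b = (i, j) if i <= j else (j, i)
    return np.random.default_rng([int(seed), _TAG_RAUPCRICK, int(a), int(b)])


def _draw_site_null(
    rng: np.random.Generator,
    n_reps: int,
    log_occ: np.ndarray,
    pool_counts: np.ndarray,
    richness: int,
    total: int,
) -> np.ndarray:
    """Null assemblages for one site: (n_reps, n_pool) integer counts.

    Taxa are chosen without replacement with probability proportional to
    occupancy via Gumbel-top-k on ``log_occ`` (zero-occupancy taxa have
    ``-inf`` and are never chosen); individuals are then allocated by a
    multinomial with weights proportional to pooled abundance.
    """
    n_pool = log_occ.size
    keys = log_occ[None, :] + rng.gumbel(size=(n_reps, n_pool))
    sel = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    out = np.zeros((n_reps, n_pool), dtype=np.int64)
    for r in range(n_reps):
        cols = sel[r]
        w = pool_counts[cols]
        out[r, cols] = rng.multinomial(total, w / w.sum())
    return out


def rc_bray(
    counts_k: np.ndarray,
    counts_m: np.ndarray,
    occupancy: np.ndarray,
    pool_counts: np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
) -> float:
    """Raup-Crick metric on Bray-Curtis for one site pair, in [-1, 1].

    RC = 2 * [ (#null < obs + 0.5 * #null == obs) / n_reps - 0.5 ].  Ties
    receive half weight, the standard Raup-Crick convention.

    Parameters
    ----------
    counts_k, counts_m :
        Integer abundance vectors over the pool order.  Real-valued tables
        are rounded (with a warning) because the null allocates discrete
        individuals.
    occupancy, pool_counts :
        Regional weights: per-taxon number of occupied sites and pooled
        abundance, both over the same pool order.
    """
    counts_k = np.asarray(counts_k, dtype=float)
    counts_m = np.asarray(counts_m, dtype=float)
    if not (
        np.allclose(counts_k, np.round(counts_k), atol=1e-9)
        and np.allclose(counts_m, np.round(counts_m), atol=1e-9)
    ):
        warnings.warn(
            "Raup-Crick null requires integer abundances; rounding",
            UserWarning,
            stacklevel=2,
        )
    obs = bray_curtis(counts_k, counts_m)
    occupancy = np.asarray(occupancy, dtype=float)
    pool_counts = np.asarray(pool_counts, dtype=float)
    n_available = int((occupancy > 0).sum())
    with np.errstate(divide="ignore"):
        log_occ = np.log(occupancy)
    null = np.empty(n_reps, dtype=float)
    sides = []
    for c in (counts_k, counts_m):
        richness = int((c > 0).sum())
        if richness > n_available:
            raise ValueError(
                f"site richness {richness} exceeds pool size {n_available}"
            )
        total = int(round(c.sum()))
        sides.append(_draw_site_null(rng, n_reps, log_occ, pool_counts, richness, total))
    a, b = sides
    # vectorized Bray-Curtis between paired null assemblages
    denom = a.sum(axis=1) + b.sum(axis=1)
    null = 1.0 - 2.0 * np.minimum(a, b).sum(axis=1) / denom
    less = int((null < obs - 1e-12).sum())
    equal = int(np.isclose(null, obs, rtol=0.0, atol=1e-12).sum())
    return float(2.0 * ((less + 0.5 * equal) / n_reps - 0.5))


def classify_pair(ses: float, rc: float | None, cfg: NullConfig) -> str:
    """Five-way process label for one site pair.

    Strictly-greater thresholds as printed: ses > cut -> heterogeneous
    selection; ses < -cut -> homogeneous selection; otherwise RC > cut ->
    dispersal limitation; RC < -cut -> homogenizing dispersal; the
    remainder is drift.  Boundary values fall through to the next rule.
    """
    if ses is None or np.isnan(ses):
        raise ValueError("classify_pair needs a non-degenerate SES")
    if ses > cfg.ses_cut:
        return "heterogeneous_selection"
    if ses < -cfg.ses_cut:
        return "homogeneous_selection"
    if rc is None or np.isnan(rc):
        raise ValueError("RC is required when |SES| is within the selection band")
    if rc > cfg.rc_cut:
        return "dispersal_limitation"
    if rc < -cfg.rc_cut:
        return "homogenizing_dispersal"
    return "drift"
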