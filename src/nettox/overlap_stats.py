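"""Significance of multi-list overlap.

Two complementary nulls are provided: an exact hypergeometric tail on a
two-set reduction of the three-way design (phyper-style, upper tail), and a
structured permutation null in which size-matched random subsets of the
measured-gene background are redrawn and the three-way overlap recomputed.
Fold enrichment is the observed overlap divided by the permutation-null
mean. The permutation p carries a +1 pseudo-count on both numerator and
denominator, so it can never be exactly zero.

The three-way-to-two-set hypergeometric reduction is a modelling choice,
not a theorem: the default takes K = |disease ∩ chemical| successes and
n = |DEG| draws from a background of size N, with the observed three-way
overlap as k. The roles are exposed as arguments so callers can swap them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats

from ._rng import substream

DEFAULT_N_PERM = 10_000


@dataclass
class OverlapResult:
    k_obs: int
    set_sizes: tuple[int, int, int]
    background_size: int
    p_hyper: float
    p_perm: float
    fold_enrichment: float
    null_mean: float
    null_sd: float
    n_perm: int
    seed: int
    null_hist: dict[int, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["null_hist"] = {str(k): v for k, v in sorted(self.null_hist.items())}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n) <= N):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if K > N or n > N:
        raise ValueError("set sizes exceed background")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def permute_overlap(
    set_a: set[str],
    set_b: set[str],
    set_c: set[str],
    background: set[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    resample: str = "all",
) -> OverlapResult:
    """Permutation test of the three-way overlap |A ∩ B ∩ C|.

    ``resample="all"`` redraws all three sets as uniform subsets of the
    background matching the observed cardinalities (most conservative);
    ``resample="c_only"`` keeps A and B fixed and redraws only C (the DEG
    list in the default pipeline wiring).

    The hypergeometric tail reported alongside uses K = |A ∩ B|, n = |C|,
    N = |background|.
    """
    background_list = sorted(background)
    N = len(background_list)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for name, s in (("A", set_a), ("B", set_b), ("C", set_c)):
        stray = set(s) - set(background)
        if stray:
            raise ValueError(
                f"set {name} not contained in background; offending symbols: {sorted(stray)[:10]}"
            )
    if resample not in {"all", "c_only"}:
        raise ValueError("resample must be 'all' or 'c_only'")

    k_obs = len(set_a & set_b & set_c)
    sizes = (len(set_a), len(set_b), len(set_c))
    rng = substream(seed, "permute_overlap")

    index = {g: i for i, g in enumerate(background_list)}
    mask_a = np.zeros(N, bool)
    mask_a[[index[g] for g in set_a]] = True
    mask_b = np.zeros(N, bool)
    mask_b[[index[g] for g in set_b]] = True
    fixed_ab = mask_a & mask_b

    k_null = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        mc = np.zeros(N, bool)
        mc[rng.choice(N, sizes[2], replace=False)] = True
        if resample == "all":
            ma = np.zeros(N, bool)
            ma[rng.choice(N, sizes[0], replace=False)] = True
            mb = np.zeros(N, bool)
            mb[rng.choice(N, sizes[1], replace=False)] = True
            k_null[b] = int(np.count_nonzero(ma & mb & mc))
        else:
            k_null[b] = int(np.count_nonzero(fixed_ab & mc))

    null_mean = float(k_null.mean())
    null_sd = float(k_null.std(ddof=1)) if n_perm > 1 else 0.0
    p_perm = (1.0 + float(np.count_nonzero(k_null >= k_obs))) / (n_perm + 1.0)
    fold = float(k_obs / null_mean) if null_mean > 0 else np.inf if k_obs > 0 else np.nan
    p_hyper = hypergeom_tail(k_obs, len(set_a & set_b), sizes[2], N)
    values, counts = np.unique(k_null, return_counts=True)
    return OverlapResult(
        k_obs=k_obs,
        set_sizes=sizes,
        background_size=N,
        p_hyper=p_hyper,
        p_perm=float(p_perm),
        fold_enrichment=fold,
        null_mean=null_mean,
        null_sd=null_sd,
        n_perm=n_perm,
        seed=seed,
        null_hist={int(v): int(c) for v, c in zip(values, counts)},
    )
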