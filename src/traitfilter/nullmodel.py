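"""Richness-conditioned null model and standardized effect size of trait
ranges (sesRange).

For each cup sample with k individuals, the null distribution of the trait
range is built by drawing k individuals without replacement from the
regional pool (all captured individuals of the taxon across the whole
gradient) B times (default 1,000) and recording the range of each draw.
When the number of distinct subsets C(n, k) is small the full distribution
is computed exactly instead of sampled: only the minimum and maximum of a
subset matter for the range, so the exhaustive distribution is obtained by
counting, for every ordered pair of pool values, the C(j-i-1, k-2) subsets
having them as extremes.

Two standardizations are reported for every sample:

* ``ses_paper = (obsRange - nullMean) / nullMean`` — the ratio form in
  which sesRange is conventionally printed, and
* ``ses_sd = (obsRange - nullMean) / nullSD`` — the z-score form, the only
  one under which the two-tailed |SES| >= 1.96 significance rule is
  probabilistically meaningful.  ``sd`` is therefore the default mode.

Negative significant SES values are classified as strong environmental
filters (narrower trait ranges than expected), positive significant values
as weak filters, everything else as consistent with the null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CupSample, trait_column, trait_range
from .errors import InputError, UndefinedSESError

DEFAULT_B = 1000
DEFAULT_THRESHOLD = 1.96
#: exhaustive enumeration replaces Monte-Carlo sampling when C(n, k) is
#: at most this many subsets
EXHAUSTIVE_CAP = 10_000

SES_MODES = ("sd", "paper_mean")

STRONG_FILTER = "strong_filter"
WEAK_FILTER = "weak_filter"
CONSISTENT = "consistent_with_null"


@dataclass
class RegionalPool:
    """All individual trait values of one taxon for one trait."""

    taxon: str
    trait: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise InputError("regional pool must be nonempty")
        if not np.all(np.isfinite(self.values)):
            raise InputError("regional pool contains non-finite trait values")

    @classmethod
    def from_table(cls, table: pd.DataFrame, taxon: str, trait: str) -> "RegionalPool":
        sub = table[table["taxon"] == taxon]
        return cls(taxon, trait, sub[trait_column(trait)].to_numpy(dtype=float))

    @property
    def size(self) -> int:
        return int(self.values.size)


@dataclass
class NullDistribution:
    """Null distribution of the trait range for draws of k individuals."""

    trait: str
    k: int
    B: int
    null_ranges: np.ndarray
    weights: np.ndarray | None
    null_mean: float
    null_sd: float
    exhaustive: bool


@dataclass
class SESResult:
    sample_id: str
    trait: str
    k: int
    obs_range: float
    null_mean: float
    null_sd: float
    ses_paper: float
    ses_sd: float
    mode_used: str
    threshold: float
    significant: bool
    classification: str


# ----------------------------------------------------------------------

def _exhaustive_ranges(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the range via min/max pair counting."""
    x = np.sort(values)
    n = x.size
    if k == n:
        return np.array([x[-1] - x[0]]), np.array([1.0])
    i, j = np.triu_indices(n, k=1)
    gaps = j - i - 1
    with np.errstate(over="ignore"):
        w = np.array([math.comb(int(g), k - 2) if g >= k - 2 else 0 for g in gaps],
                     dtype=float)
    keep = w > 0
    return (x[j[keep]] - x[i[keep]]), w[keep]


def _sampled_ranges(values: np.ndarray, k: int, B: int,
                    rng: np.random.Generator) -> np.ndarray:
    """B ranges of k-subsets drawn uniformly without replacement."""
    n = values.size
    out = np.empty(B)
    # random-key trick: the k smallest keys of a uniform vector index a
    # uniformly random k-subset; chunked to bound memory
    chunk = max(1, int(4_000_000 // n))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        draws = values[idx]
        out[done:done + b] = draws.max(axis=1) - draws.min(axis=1)
        done += b
    return out


def build_null_distribution(pool: RegionalPool, k: int, B: int = DEFAULT_B,
                            rng: np.random.Generator | None = None,
                            exhaustive_cap: int = EXHAUSTIVE_CAP) -> NullDistribution:
    """Null range distribution for samples of k individuals from the pool.

    Uses exhaustive enumeration when C(pool, k) <= ``exhaustive_cap``
    (flagged on the result), otherwise B Monte-Carlo draws without
    replacement.
    """
    n = pool.size
    if not 2 <= k <= n:
        raise InputError(
            f"individual richness k={k} out of bounds for pool of {n} "
            "(an observed sample cannot exceed the regional pool)"
        )
    if B < 1:
        raise InputError(f"B must be >= 1, got {B}")
    n_subsets = math.comb(n, k)
    if n_subsets <= exhaustive_cap:
        ranges, weights = _exhaustive_ranges(pool.values, k)
        mean = float(np.average(ranges, weights=weights))
        var = float(np.average((ranges - mean) ** 2, weights=weights))
        return NullDistribution(pool.trait, k, int(n_subsets), ranges, weights,
                                mean, math.sqrt(max(var, 0.0)), True)
    if rng is None:
        rng = np.random.default_rng()
    ranges = _sampled_ranges(pool.values, k, B, rng)
    mean = float(ranges.mean())
    sd = float(ranges.std())  # population SD over the B draws
    return NullDistribution(pool.trait, k, B, ranges, None, mean, sd, False)


def ses_range(obs_range: float, nulldist: NullDistribution, mode: str = "sd",
              threshold: float = DEFAULT_THRESHOLD,
              sample_id: str = "") -> SESResult:
    """Standardized effect size of an observed trait range.

    Both normalizations are computed; significance and the filtering
    classification are evaluated under ``mode`` (``sd`` or ``paper_mean``)
    against ``threshold`` (default 1.96, the two-tailed 5% z bound).
    """
    if mode not in SES_MODES:
        raise InputError(f"mode must be one of {SES_MODES}, got {mode!r}")
    if obs_range < 0:
        raise InputError(f"obs_range must be >= 0, got {obs_range}")
    delta = obs_range - nulldist.null_mean
    if mode == "paper_mean" and nulldist.null_mean == 0:
        raise UndefinedSESError("null mean is zero: paper_mean SES undefined")
    if mode == "sd" and nulldist.null_sd == 0:
        raise UndefinedSESError("null SD is zero: sd-normalized SES undefined")
    ses_paper = delta / nulldist.null_mean if nulldist.null_mean > 0 else math.nan
    ses_sd = delta / nulldist.null_sd if nulldist.null_sd > 0 else math.nan
    value = ses_sd if mode == "sd" else ses_paper
    significant = bool(abs(value) >= threshold)
    if significant and value < 0:
        classification = STRONG_FILTER
    elif significant:
        classification = WEAK_FILTER
    else:
        classification = CONSISTENT
    return SESResult(sample_id, nulldist.trait, nulldist.k, float(obs_range),
                     nulldist.null_mean, nulldist.null_sd, float(ses_paper),
                     float(ses_sd), mode, threshold, significant, classification)


def classify_filtering(ses: SESResult) -> str:
    """Filtering label from the sign/threshold rule on the SES."""
    value = ses.ses_sd if ses.mode_used == "sd" else ses.ses_paper
    if abs(value) >= ses.threshold:
        return STRONG_FILTER if value < 0 else WEAK_FILTER
    return CONSISTENT


def ses_table(samples: list[CupSample], pool: RegionalPool, trait: str,
              B: int = DEFAULT_B, mode: str = "sd",
              threshold: float = DEFAULT_THRESHOLD,
              rng: np.random.Generator | None = None,
              null_cache: dict | None = None) -> pd.DataFrame:
    """SES of the trait range for every eligible sample (n >= 2).

    Null distributions are built once per distinct individual richness k
    and shared across samples (``null_cache`` may be supplied to share
    them across calls for the same pool/B).  Samples of another taxon than
    the pool's are rejected; samples with fewer than two individuals are
    skipped.
    """
    if rng is None:
        rng = np.random.default_rng()
    if null_cache is None:
        null_cache = {}
    eligible = [s for s in samples if s.n_individuals >= 2]
    for s in eligible:
        if s.taxon != pool.taxon:
            raise InputError(
                f"sample {s.sample_id} is taxon {s.taxon!r} but the pool is "
                f"{pool.taxon!r}"
            )
    if not eligible:
        warnings.warn("no eligible samples (all below 2 individuals); "
                      "returning an empty SES table", stacklevel=2)
    rows = []
    # build null distributions in sorted-k order so results are independent
    # of the order samples arrive in
    for k in sorted({s.n_individuals for s in eligible}):
        if (trait, k) not in null_cache:
            null_cache[(trait, k)] = build_null_distribution(pool, k, B=B, rng=rng)
    for s in eligible:
        nd = null_cache[(trait, s.n_individuals)]
        res = ses_range(trait_range(s, trait), nd, mode=mode,
                        threshold=threshold, sample_id=s.sample_id)
        rows.append((res.sample_id, s.taxon, s.life_zone, s.site_id, s.habitat,
                     s.season, trait, res.k, res.obs_range, res.null_mean,
                     res.null_sd, res.ses_paper, res.ses_sd, res.significant,
                     res.classification))
    return pd.DataFrame(rows, columns=[
        "sample_id", "taxon", "life_zone", "site_id", "habitat", "season",
        "trait", "k", "obs_range", "null_mean", "null_sd", "ses_paper",
        "ses_sd", "significant", "classification",
    ])
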