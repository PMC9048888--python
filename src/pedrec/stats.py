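"""Rates, tests and regional profiles for recombination events.

Covers the descriptive layer of the analysis: per-site NCO rates, exact
binomial tests of GC-biased gene conversion, telomere-distance profiles of
event counts, recombination-rate profiles around focal points, the
distal/proximal rate comparison, parental-age associations, and rescaling
of an external (LD-based) rate map to a pedigree map total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, mannwhitneyu


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# rates and tests
# ---------------------------------------------------------------------------

def nco_rate(n_converted_sites: int, n_informative_site_meioses: int) -> float:
    """Conversion rate per informative site per meiosis.

    The denominator is the number of informative-site observations summed
    over meioses (the detectable fraction of the genome).
    """
    if n_informative_site_meioses <= 0:
        raise StatsError("denominator must be positive")
    return n_converted_sites / n_informative_site_meioses


def sex_averaged_rate(paternal: float, maternal: float) -> float:
    return 0.5 * (paternal + maternal)


def gbgc_test(n_gc: int, n_informative: int, p0: float = 0.5,
              tail: str = "upper") -> float:
    """One-tailed exact binomial P for transmission bias toward G/C.

    ``tail="upper"`` tests bias greater than p0 (P(X >= n_gc)); "lower"
    tests bias smaller than p0.
    """
    if n_informative <= 0:
        raise StatsError("n_informative must be positive")
    if not 0 < p0 < 1:
        raise StatsError("p0 must be in (0, 1)")
    if not 0 <= n_gc <= n_informative:
        raise StatsError("need 0 <= n_gc <= n_informative")
    alt = {"upper": "greater", "lower": "less"}[tail]
    return float(binomtest(n_gc, n_informative, p0, alternative=alt).pvalue)


# ---------------------------------------------------------------------------
# regional profiles
# ---------------------------------------------------------------------------

def telomere_profile(events: pd.DataFrame, chrom_lengths: dict[str, int],
                     window_bp: int = 2_000_000,
                     step_bp: int = 500_000) -> pd.DataFrame:
    """Rolling event counts by distance to the nearest chromosome end.

    ``events`` needs columns chrom, pos and optionally strata columns
    (e.g. sex, kind) which are preserved as group keys.  Windows of
    ``window_bp`` advance by ``step_bp`` along the distance axis; counts
    are summed over chromosomes.
    """
    need = {"chrom", "pos"}
    if not need.issubset(events.columns):
        raise StatsError("events needs chrom and pos columns")
    ev = events.copy()
    lens = ev["chrom"].map(chrom_lengths)
    if lens.isna().any():
        raise StatsError("event chromosome missing from chrom_lengths")
    ev["dist"] = np.minimum(ev["pos"], lens - ev["pos"] + 1)
    max_dist = int(max(chrom_lengths.values()) // 2)
    starts = np.arange(0, max_dist + 1, step_bp)
    strata = [c for c in ev.columns if c not in ("chrom", "pos", "dist")]
    rows = []
    groups = ev.groupby(strata) if strata else [((), ev)]
    for key, sub in groups:
        d = sub["dist"].to_numpy()
        for s in starts:
            cnt = int(np.sum((d >= s) & (d < s + window_bp)))
            row = {"window_start": int(s), "count": cnt}
            if strata:
                key_t = key if isinstance(key, tuple) else (key,)
                row.update(dict(zip(strata, key_t)))
            rows.append(row)
    return pd.DataFrame(rows)


def _rates_at(rmap: pd.DataFrame, chrom: str,
              positions: np.ndarray) -> np.ndarray:
    sub = rmap[rmap["chrom"] == chrom]
    if sub.empty:
        return np.full(np.asarray(positions).shape, np.nan)
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    rates = sub["rate"].to_numpy()
    idx = np.searchsorted(starts, positions, side="right") - 1
    out = np.full(positions.shape, np.nan)
    ok = (idx >= 0) & (positions <= ends[np.clip(idx, 0, None)])
    out[ok] = rates[idx[ok]]
    return out


def rate_around_points(rmap: pd.DataFrame,
                       points: Sequence[tuple[str, int]],
                       flank_bp: int = 50_000,
                       step_bp: int = 1_000
                       ) -> tuple[pd.DataFrame, np.ndarray]:
    """Local rate profiles around focal points on a common offset grid.

    Returns (per-point profiles as a DataFrame with one row per point and
    one column per offset, mean profile across points).  Points outside
    map coverage are skipped with a warning row omitted.
    """
    offsets = np.arange(-flank_bp, flank_bp + 1, step_bp)
    profiles = []
    kept = []
    for chrom, pos in points:
        r = _rates_at(rmap, chrom, pos + offsets)
        if np.isnan(r).all():
            continue
        profiles.append(r)
        kept.append((chrom, pos))
    if not profiles:
        return pd.DataFrame(columns=list(offsets)), np.array([])
    prof = pd.DataFrame(profiles, columns=list(offsets),
                        index=pd.MultiIndex.from_tuples(
                            kept, names=["chrom", "pos"]))
    return prof, np.nanmean(np.asarray(profiles, dtype=float), axis=0)


def distal_proximal_test(rmap: pd.DataFrame, chrom_lengths: dict[str, int],
                         cutoff_bp: int = 10_000_000
                         ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of distal vs proximal interval rates.

    Distal intervals lie within ``cutoff_bp`` of a chromosome end.
    Returns (U statistic, P value); exact for small samples without ties,
    normal approximation with tie correction otherwise (scipy default).
    """
    mids = (rmap["start"] + rmap["end"]) / 2.0
    lens = rmap["chrom"].map(chrom_lengths)
    dist = np.minimum(mids, lens - mids + 1)
    distal = rmap.loc[dist <= cutoff_bp, "rate"].to_numpy()
    proximal = rmap.loc[dist > cutoff_bp, "rate"].to_numpy()
    if distal.size == 0 or proximal.size == 0:
        raise StatsError("one stratum is empty")
    res = mannwhitneyu(distal, proximal, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def age_association(counts: Sequence[int], ages: Sequence[float],
                    exposures: Sequence[float] | None = None
                    ) -> tuple[float, float]:
    """Poisson regression of per-meiosis event counts on parental age.

    Uses a log link with log(exposure) offset (exposure: informative sites
    per meiosis).  Returns (slope per year, two-sided Wald P).
    """
    import statsmodels.api as sm

    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if counts.size < 3 or np.unique(ages).size < 2:
        raise StatsError("need >= 3 meioses with >= 2 distinct ages")
    X = sm.add_constant(ages)
    offset = None
    if exposures is not None:
        offset = np.log(np.asarray(exposures, dtype=float))
    fit = sm.GLM(counts, X, family=sm.families.Poisson(),
                 offset=offset).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


# ---------------------------------------------------------------------------
# rate maps
# ---------------------------------------------------------------------------

def validate_rate_map(rmap: pd.DataFrame) -> pd.DataFrame:
    need = {"chrom", "start", "end", "rate"}
    if not need.issubset(rmap.columns):
        raise StatsError(f"rate map needs columns {sorted(need)}")
    if (rmap["rate"] < 0).any():
        raise StatsError("rates must be >= 0")
    out = rmap.sort_values(["chrom", "start"]).reset_index(drop=True)
    for _, sub in out.groupby("chrom"):
        if (sub["start"].to_numpy()[1:] <= sub["end"].to_numpy()[:-1]).any():
            raise StatsError("rate-map intervals overlap")
    return out


def map_total_cM(rmap: pd.DataFrame) -> float:
    """Total map length implied by cM/Mb rates over interval lengths."""
    span_mb = (rmap["end"] - rmap["start"] + 1) / 1e6
    return float((rmap["rate"] * span_mb).sum())


def rescale_map(rmap: pd.DataFrame, target_total_cM: float) -> pd.DataFrame:
    """Multiply all rates by a constant so the map totals target_total_cM."""
    rmap = validate_rate_map(rmap)
    total = map_total_cM(rmap)
    if total <= 0:
        raise StatsError("cannot rescale a zero-length map")
    out = rmap.copy()
    out["rate"] = out["rate"] * (target_total_cM / total)
    return out
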