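"""Gene-conversion tract-length models and the k-mer-overlap likelihood.

A noncrossover (NCO) gene-conversion tract is observed only through the
informative markers it converts: the latent tract of length ``k`` is
compatible with every window of ``k`` consecutive base pairs that covers
all converted markers and no nonconverted ones.  Writing ``o_k`` for the
number of such windows for one tract, and ``e_k`` for the number of
``k``-windows on a chromosome that would have converted at least one
nonconverted marker, the log-likelihood of the data under a tract-length
distribution with per-bp initiation probability ``f_k`` is

    sum_tracts log( sum_k f_k o_k )  -  sum_{meiosis,chrom} sum_k f_k e_k

where the second term is the exponential approximation to
``prod_k (1 - f_k)^{e_k}``.  ``f_k = r Pr(k) / mean`` so that the expected
converted bp per bp equals the initiation rate ``r``.

Two families are supported: a single truncated geometric, and a mixture of
two truncated geometrics parameterised by the mixing weight ``alpha`` and
the means ``m1 <= m2`` of the nontruncated components.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

DEFAULT_TRUNCATION = 10_000
DEFAULT_NCO_RATE = 7.52e-6
#: chi^2(1 df) 95% half-width on the log-likelihood scale
PROFILE_DROP = 1.92


def two_significant_digit_grid(lo: int = 10, hi: int = 100_000) -> np.ndarray:
    """All integers with at most two significant digits in [lo, hi]."""
    vals: list[int] = []
    scale = 1
    while scale * 10 <= hi:
        for lead in range(10, 100):
            v = lead * scale
            if lo <= v <= hi:
                vals.append(v)
        scale *= 10
    if lo <= hi and hi == 10 ** int(round(math.log10(hi))):
        vals.append(hi)
    return np.unique(np.asarray(vals, dtype=np.int64))


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class TractLengthModel:
    """Tract-length distribution over 1..truncation.

    ``family`` is "geometric" (single component, mean ``m1``) or "mixture2"
    (weight ``alpha`` on a component with nontruncated mean ``m1``, weight
    ``1 - alpha`` on mean ``m2``).  ``rate_per_bp`` is the per-bp per-meiosis
    initiation probability of a tract.
    """

    family: str = "mixture2"
    alpha: float = 0.998
    m1: float = 24.0
    m2: float = 4300.0
    truncation: int = DEFAULT_TRUNCATION
    rate_per_bp: float = DEFAULT_NCO_RATE

    def __post_init__(self) -> None:
        if self.family not in ("geometric", "mixture2"):
            raise ModelError(f"unknown family {self.family!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ModelError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.m1 < 1:
            raise ModelError(f"m1 must be >= 1, got {self.m1}")
        if self.family == "mixture2" and self.m2 < self.m1:
            raise ModelError(f"need m1 <= m2, got {self.m1} > {self.m2}")
        if self.truncation < 1:
            raise ModelError(f"truncation must be >= 1, got {self.truncation}")
        if not self.rate_per_bp > 0:
            raise ModelError(f"rate_per_bp must be > 0, got {self.rate_per_bp}")

    # -- mass function ---------------------------------------------------

    def _raw_pmf(self) -> np.ndarray:
        """Unnormalised mixture of nontruncated geometric pmfs on 1..T."""
        k = np.arange(1, self.truncation + 1, dtype=np.float64)
        out = _geom_pmf(k, self.m1)
        if self.family == "mixture2":
            out = self.alpha * out + (1.0 - self.alpha) * _geom_pmf(k, self.m2)
        return out

    def pmf(self) -> np.ndarray:
        """Truncated-renormalised mass function, index i = length i+1."""
        raw = self._raw_pmf()
        return raw / raw.sum()

    def mean(self) -> float:
        """Mean of the truncated-renormalised distribution."""
        p = self.pmf()
        k = np.arange(1, self.truncation + 1, dtype=np.float64)
        return float(k @ p)

    def initiation_probs(self) -> np.ndarray:
        """f_k for k = 1..T; satisfies sum_k k f_k = rate_per_bp."""
        p = self.pmf()
        return self.rate_per_bp * p / self.mean()

    def tail_fraction(self, x_bp: float, weight: str = "tracts",
                      truncated: bool = True) -> float:
        """P(length > x) under the model.

        ``weight="tracts"`` counts tracts; ``weight="sites"`` weights each
        length class by the number of base pairs it converts.  With
        ``truncated=False`` the nontruncated component mixture is used.
        """
        if x_bp < 0:
            raise ModelError("x_bp must be >= 0")
        if weight not in ("tracts", "sites"):
            raise ModelError(f"unknown weight {weight!r}")
        if truncated:
            p = self.pmf()
            k = np.arange(1, self.truncation + 1, dtype=np.float64)
            w = k * p if weight == "sites" else p
            return float(w[k > x_bp].sum() / w.sum())
        # closed-form nontruncated tails
        comps = [(1.0, self.m1)] if self.family == "geometric" else [
            (self.alpha, self.m1), (1.0 - self.alpha, self.m2)]
        num = den = 0.0
        x = math.floor(x_bp)
        for w_c, m in comps:
            q = 1.0 - 1.0 / m
            surv = q ** x
            if weight == "tracts":
                num += w_c * surv
                den += w_c
            else:
                # E[K 1(K > x)] = q^x (x + 1/p) for geometric(p)
                num += w_c * surv * (x + m)
                den += w_c * m
        return num / den

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw tract lengths by inverse-CDF within each truncated component."""
        if self.family == "geometric":
            comp = np.zeros(size, dtype=np.int64)
        else:
            # component weights adjusted for joint truncation: a component's
            # share of the truncated mixture is proportional to its weight
            # times its nontruncated mass below the truncation point
            w = np.empty(2)
            for ci, (a, m) in enumerate(((self.alpha, self.m1),
                                         (1.0 - self.alpha, self.m2))):
                mass = 1.0 if m <= 1.0 else \
                    1.0 - (1.0 - 1.0 / m) ** self.truncation
                w[ci] = a * mass
            comp = (rng.random(size) >= w[0] / w.sum()).astype(np.int64)
        out = np.empty(size, dtype=np.int64)
        for ci, m in enumerate((self.m1, self.m2)):
            mask = comp == ci
            n = int(mask.sum())
            if n == 0:
                continue
            if m <= 1.0:
                out[mask] = 1
                continue
            q = 1.0 - 1.0 / m
            # truncated inverse CDF: F(k) = (1 - q^k) / (1 - q^T)
            u = rng.random(n) * (1.0 - q ** self.truncation)
            k = np.ceil(np.log1p(-u) / math.log(q)).astype(np.int64)
            out[mask] = np.clip(k, 1, self.truncation)
        return out


def _geom_pmf(k: np.ndarray, m: float) -> np.ndarray:
    """Nontruncated geometric pmf with mean m (success prob 1/m)."""
    if m <= 1.0:
        return np.where(k == 1, 1.0, 0.0)
    p = 1.0 / m
    q = 1.0 - p
    return p * np.exp((k - 1) * math.log(q))


def initiation_prob(k: int, model: TractLengthModel) -> float:
    """Per-bp probability that a tract of exactly length k initiates at a bp."""
    if not 1 <= k <= model.truncation:
        raise ModelError(
            f"k={k} outside 1..{model.truncation} for this model")
    return float(model.initiation_probs()[k - 1])


# ---------------------------------------------------------------------------
# k-mer counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TractObservation:
    """An observed tract: converted markers pinned between nonconverted flanks.

    Positions are 1-based bp.  ``left_flank < first <= last < right_flank``.
    A missing flank at a chromosome boundary is encoded by clipping to
    position 0 (left) or chrom_length + 1 (right), so windows are bounded by
    the chromosome instead of a marker.
    """

    left_flank: int
    first: int
    last: int
    right_flank: int
    meiosis: str = ""
    chrom: str = ""

    def __post_init__(self) -> None:
        if not self.left_flank < self.first <= self.last < self.right_flank:
            raise ModelError(
                f"invalid tract geometry {self.left_flank} < {self.first} "
                f"<= {self.last} < {self.right_flank}")

    @property
    def span(self) -> int:
        return self.last - self.first + 1


def observed_kmer_counts(obs: TractObservation,
                         k_max: int | None = None) -> dict[int, int]:
    """o_k: number of k-windows covering all converted, no flanking markers.

    Closed form: a window of length k starting at s covers the tract iff
    s <= first, s + k - 1 >= last, s > left_flank and s + k - 1 < right_flank.
    """
    s = obs.span
    hi = obs.right_flank - obs.left_flank - 1
    if k_max is not None:
        hi = min(hi, k_max)
    out: dict[int, int] = {}
    for k in range(s, hi + 1):
        lo_start = max(obs.last - k + 1, obs.left_flank + 1)
        hi_start = min(obs.first, obs.right_flank - k)
        c = hi_start - lo_start + 1
        if c > 0:
            out[k] = c
    return out


def excluded_kmer_counts(positions: Sequence[int], chrom_length: int,
                         k: int) -> int:
    """e_k for one k: k-window starts that cover >= 1 nonconverted marker."""
    return int(excluded_counts_vector(positions, chrom_length, k)[k - 1])


def excluded_counts_vector(positions: Sequence[int], chrom_length: int,
                           t_max: int) -> np.ndarray:
    """e_k for k = 1..t_max as a vector.

    A window of length k starting at s (1 <= s <= L-k+1) covers marker p iff
    p-k+1 <= s <= p.  The union over markers is computed from the sorted
    gap decomposition, with an explicit correction for starts clipped off by
    the right chromosome boundary.
    """
    L = int(chrom_length)
    pos = np.unique(np.asarray(positions, dtype=np.int64))
    if pos.size and (pos[0] < 1 or pos[-1] > L):
        raise ModelError("marker positions outside [1, chrom_length]")
    ks = np.arange(1, t_max + 1, dtype=np.int64)
    if pos.size == 0:
        return np.zeros(t_max, dtype=np.float64)
    gaps = np.diff(np.concatenate(([0], pos)))
    sg = np.sort(gaps)
    cs = np.concatenate(([0], np.cumsum(sg)))
    idx = np.searchsorted(sg, ks, side="right")
    base = cs[idx] + ks * (pos.size - idx)  # union clipped at left only
    e = base.astype(np.float64)
    # windows of length k > L do not exist
    e[ks > L] = 0.0
    # Right-boundary correction: subtract covered starts in (L-k+1, L].
    # Only markers q with q > L - t_max can lie right of the last valid
    # start, and for a given k those are q > w = L - k + 1.  The first such
    # marker covers all of (w, q]; each later one adds min(gap, k) as in the
    # left-clipped union.  Each marker's contribution is piecewise linear in
    # k, so accumulate per marker over the whole k vector.
    kv = np.minimum(ks, L)
    tail = pos[pos > L - min(t_max, L)]
    cov = np.zeros(t_max, dtype=np.float64)
    for j, q in enumerate(tail):
        q = int(q)
        c_j = L - q + 2  # smallest k with q > L - k + 1
        if j == 0:
            # q is the first (and leftmost) tail marker whenever k >= c_j
            cov += np.where(kv >= c_j, kv - (L + 1 - q), 0.0)
        else:
            c_prev = L - int(tail[j - 1]) + 2
            d = q - int(tail[j - 1])
            # q first tail marker: c_j <= k < c_prev; otherwise min(gap, k)
            first = (kv >= c_j) & (kv < c_prev)
            cov += np.where(first, kv - (L + 1 - q), 0.0)
            cov += np.where(kv >= c_prev, np.minimum(d, kv), 0.0)
    e -= cov
    e[ks > L] = 0.0
    return e


@dataclass
class KmerData:
    """Likelihood inputs: observed tracts plus aggregated exclusion counts.

    ``e_total[k-1]`` is e_k summed over every (meiosis, chromosome) pair,
    which is all the likelihood needs since the exclusion term is linear.
    """

    tracts: list[TractObservation]
    e_total: np.ndarray
    rate_per_bp: float = DEFAULT_NCO_RATE

    @property
    def t_max(self) -> int:
        return int(self.e_total.shape[0])

    @classmethod
    def build(cls, tracts: Iterable[TractObservation],
              nonconverted: Iterable[tuple[Sequence[int], int]],
              t_max: int = DEFAULT_TRUNCATION,
              rate_per_bp: float = DEFAULT_NCO_RATE) -> "KmerData":
        """Assemble from tracts and per-(meiosis, chrom) nonconverted markers.

        ``nonconverted`` yields (marker_positions, chrom_length) pairs, one
        per meiosis-chromosome.
        """
        e = np.zeros(t_max, dtype=np.float64)
        for positions, length in nonconverted:
            e += excluded_counts_vector(positions, length, t_max)
        return cls(tracts=list(tracts), e_total=e, rate_per_bp=rate_per_bp)

    def restrict(self, max_span: int) -> "KmerData":
        """Keep tracts with span <= max_span; cap k at max_span."""
        kept = [t for t in self.tracts if t.span <= max_span]
        t_max = min(self.t_max, max_span)
        return KmerData(kept, self.e_total[:t_max].copy(), self.rate_per_bp)


# -- closed-form per-component sums ----------------------------------------

def _geom_linear_sum(a: float, b: float, k1: int, k2: int, m: float) -> float:
    """sum_{k=k1}^{k2} (a + b k) q^{k-1} for q = 1 - 1/m (m > 1), else m=1."""
    if k2 < k1:
        return 0.0
    if m <= 1.0:
        return a + b * k1 if k1 == 1 else 0.0
    q = 1.0 - 1.0 / m
    lq = math.log(q)
    qk1m1 = math.exp((k1 - 1) * lq)
    qk2 = math.exp(k2 * lq)
    p = 1.0 - q
    s0 = (qk1m1 - qk2) / p
    # sum k q^{k-1} over [k1, k2] via S(n) = (1 - (n+1) q^n + n q^{n+1}) / p^2
    def s1_upto(n: int) -> float:
        qn = math.exp(n * lq)
        return (1.0 - (n + 1) * qn + n * qn * q) / (p * p)
    s1 = s1_upto(k2) - s1_upto(k1 - 1)
    return a * s0 + b * s1


def _tract_component_sum(obs: TractObservation, m: float, t_max: int) -> float:
    """sum_k g(k; m) o_k with g the nontruncated geometric pmf, k <= t_max."""
    s = obs.span
    lgap = obs.first - obs.left_flank
    rgap = obs.right_flank - obs.last
    k_lo = s
    k_hi = min(obs.right_flank - obs.left_flank - 1, t_max)
    if k_hi < k_lo:
        return 0.0
    kl = obs.last - obs.left_flank      # rising regime ends at min(kl, kr)
    kr = obs.right_flank - obs.first
    p = 1.0 if m <= 1.0 else 1.0 / m
    total = 0.0
    # rising: o_k = k - s + 1
    a1, b1 = float(1 - s), 1.0
    total += _geom_linear_sum(a1, b1, k_lo, min(k_hi, min(kl, kr)), m)
    # flat: o_k = min(lgap, rgap)
    flat_lo, flat_hi = min(kl, kr) + 1, min(max(kl, kr), k_hi)
    total += _geom_linear_sum(float(min(lgap, rgap)), 0.0, flat_lo, flat_hi, m)
    # falling: o_k = (right_flank - left_flank) - k
    fall_lo = max(kl, kr) + 1
    total += _geom_linear_sum(float(obs.right_flank - obs.left_flank), -1.0,
                              fall_lo, k_hi, m)
    return p * total


def _raw_moments(m: float, t_max: int) -> tuple[float, float]:
    """(sum_{k<=T} g(k;m), sum_{k<=T} k g(k;m)) for nontruncated geometric."""
    if m <= 1.0:
        return 1.0, 1.0
    p = 1.0 / m
    s0 = p * _geom_linear_sum(1.0, 0.0, 1, t_max, m)
    s1 = p * _geom_linear_sum(0.0, 1.0, 1, t_max, m)
    return s0, s1


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------

def _observation_prob(obs: TractObservation, f: np.ndarray) -> float:
    """sum_k f_k o_k via the piecewise-linear o_k (dense over the support)."""
    t_max = f.shape[0]
    k_lo = obs.span
    k_hi = min(obs.right_flank - obs.left_flank - 1, t_max)
    if k_hi < k_lo:
        return 0.0
    k = np.arange(k_lo, k_hi + 1, dtype=np.int64)
    lo_start = np.maximum(obs.last - k + 1, obs.left_flank + 1)
    hi_start = np.minimum(obs.first, obs.right_flank - k)
    o = np.maximum(hi_start - lo_start + 1, 0)
    return float(f[k - 1] @ o)


def log_likelihood(data: KmerData, model: TractLengthModel,
                   exact_exclusion: bool = False) -> float:
    """Log-likelihood of the tract observations under ``model``.

    ``exact_exclusion=True`` evaluates the product form
    ``prod_k (1 - f_k)^{e_k}`` instead of its exponential approximation.
    """
    if any(t.span > model.truncation for t in data.tracts):
        raise ModelError("a tract spans more than the model truncation")
    f = model.initiation_probs()
    t_max = min(data.t_max, model.truncation)
    ll = 0.0
    for obs in data.tracts:
        p_obs = _observation_prob(obs, f)
        if p_obs <= 0.0:
            warnings.warn(
                f"tract at {obs.chrom}:{obs.first}-{obs.last} has zero "
                "probability under the model", RuntimeWarning)
            return -math.inf
        ll += math.log(p_obs)
    e = data.e_total[:t_max]
    fk = f[:t_max]
    if exact_exclusion:
        ll += float(e @ np.log1p(-fk))
    else:
        ll -= float(fk @ e)
    return ll


@dataclass
class GeometricFit:
    mean: int
    loglik: float
    ci_low: int
    ci_high: int


def fit_geometric(data: KmerData, max_span: int | None = None,
                  mean_max: int = 100_000) -> GeometricFit:
    """Integer-mean MLE of a truncated geometric, with 95% likelihood CI.

    The truncation bound equals ``max_span`` (tracts longer than it are
    excluded from the data).  The CI contains every integer mean whose
    log-likelihood is within 1.92 of the maximum.
    """
    if max_span is None:
        max_span = data.t_max
    d = data.restrict(max_span)
    if not d.tracts:
        raise ModelError("no tracts with span <= max_span")
    t_max = d.t_max
    r = d.rate_per_bp

    a_cache: dict[int, float] = {}

    def ll(m: int) -> float:
        if m in a_cache:
            return a_cache[m]
        _, m_raw = _raw_moments(float(m), t_max)
        tot = 0.0
        ok = True
        for obs in d.tracts:
            a = _tract_component_sum(obs, float(m), t_max)
            if a <= 0.0:
                ok = False
                break
            tot += math.log(r * a / m_raw)
        if ok:
            b = _component_exclusion_sum(float(m), d.e_total)
            val = tot - r * b / m_raw
        else:
            val = -math.inf
        a_cache[m] = val
        return val

    min_mean = 1
    # coarse pass on the two-significant-digit grid, then integer hill climb
    grid = [m for m in two_significant_digit_grid(1, mean_max)]
    grid = sorted(set([1, 2, 3, 4, 5, 6, 7, 8, 9] + grid))
    best = max(grid, key=ll)
    m = best
    while m + 1 <= mean_max and ll(m + 1) > ll(m):
        m += 1
    while m - 1 >= min_mean and ll(m - 1) > ll(m):
        m -= 1
    lmax = ll(m)
    lo = m
    while lo - 1 >= 1 and ll(lo - 1) >= lmax - PROFILE_DROP:
        lo -= 1
    hi = m
    while hi + 1 <= mean_max and ll(hi + 1) >= lmax - PROFILE_DROP:
        hi += 1
    return GeometricFit(mean=m, loglik=lmax, ci_low=lo, ci_high=hi)


def _component_exclusion_sum(m: float, e_total: np.ndarray) -> float:
    """sum_k g(k; m) e_k over the support of e_total."""
    t_max = e_total.shape[0]
    k = np.arange(1, t_max + 1, dtype=np.float64)
    return float(_geom_pmf(k, m) @ e_total)


@dataclass
class MixtureFit:
    alpha: float
    m1: int
    m2: int
    loglik: float
    ci_m1: tuple[float, float]
    ci_m2: tuple[float, float]
    profile_m1: dict[int, float] = field(default_factory=dict)
    profile_m2: dict[int, float] = field(default_factory=dict)
    flat: bool = False

    def model(self, truncation: int, rate_per_bp: float) -> TractLengthModel:
        return TractLengthModel("mixture2", self.alpha, self.m1, self.m2,
                                truncation, rate_per_bp)


def fit_mixture(data: KmerData, max_span: int | None = None,
                grid_stride: int = 1, alpha_step: float = 0.001,
                mean_min: int = 10, mean_max: int = 100_000) -> MixtureFit:
    """Grid-search MLE of the two-component truncated-geometric mixture.

    Component means run over the two-significant-digit grid (optionally
    thinned by ``grid_stride``) with m1 <= m2; the mixing weight is
    optimised on an ``alpha_step`` lattice in [0, 1] for every mean pair.
    Profile-likelihood curves over m1 and m2 give the 95% CIs (1.92 drop).
    """
    if max_span is not None:
        data = data.restrict(max_span)
    if len(data.tracts) < 2:
        raise ModelError("mixture fit needs at least two tracts")
    t_max = data.t_max
    r = data.rate_per_bp
    means = two_significant_digit_grid(mean_min, mean_max)[::grid_stride]
    n_m = means.size
    n_t = len(data.tracts)

    # per-mean caches: tract sums, exclusion sums, raw first moments
    A = np.empty((n_m, n_t), dtype=np.float64)
    B = np.empty(n_m, dtype=np.float64)
    M = np.empty(n_m, dtype=np.float64)
    for i, m in enumerate(means):
        for j, obs in enumerate(data.tracts):
            A[i, j] = _tract_component_sum(obs, float(m), t_max)
        B[i] = _component_exclusion_sum(float(m), data.e_total)
        _, M[i] = _raw_moments(float(m), t_max)

    n_coarse = 41
    coarse = np.round(np.linspace(0.0, 1.0, n_coarse) / alpha_step) * alpha_step

    log_r_n = n_t * math.log(r)

    def ll_alphas(i: int, j: int, alphas: np.ndarray) -> np.ndarray:
        al = alphas[:, None]
        num = al * A[i] + (1.0 - al) * A[j]          # (n_a, n_t)
        mmix = alphas * M[i] + (1.0 - alphas) * M[j]
        bmix = alphas * B[i] + (1.0 - alphas) * B[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(num > 0, np.log(num), -np.inf).sum(axis=1)
        return log_r_n + t1 - n_t * np.log(mmix) - r * bmix / mmix

    pair_ll = np.full((n_m, n_m), -np.inf)
    pair_alpha = np.zeros((n_m, n_m))
    for i in range(n_m):
        for j in range(i, n_m):
            vals = ll_alphas(i, j, coarse)
            kbest = int(np.argmax(vals))
            best_ll, best_a = float(vals[kbest]), float(coarse[kbest])
            # refine on the alpha_step lattice around the coarse optimum
            lo = coarse[max(kbest - 1, 0)]
            hi = coarse[min(kbest + 1, n_coarse - 1)]
            fine = np.arange(round(lo / alpha_step),
                             round(hi / alpha_step) + 1) * alpha_step
            if fine.size > 3:
                vals_f = ll_alphas(i, j, fine)
                kf = int(np.argmax(vals_f))
                if vals_f[kf] > best_ll:
                    best_ll, best_a = float(vals_f[kf]), float(fine[kf])
            pair_ll[i, j] = best_ll
            pair_alpha[i, j] = best_a

    imax, jmax = np.unravel_index(np.argmax(pair_ll), pair_ll.shape)
    lmax = float(pair_ll[imax, jmax])
    alpha_hat = float(pair_alpha[imax, jmax])

    prof1 = {int(means[i]): float(np.max(pair_ll[i, i:])) for i in range(n_m)}
    prof2 = {int(means[j]): float(np.max(pair_ll[: j + 1, j]))
             for j in range(n_m)}

    def ci(prof: dict[int, float]) -> tuple[float, float]:
        # the threshold crossing lies between the outermost grid point still
        # above the drop and its excluded neighbour; interpolate the profile
        # on the log-mean scale rather than snapping inward to the grid
        ms = np.array(sorted(prof), dtype=np.float64)
        lls = np.array([prof[int(m)] for m in ms])
        thr = lmax - PROFILE_DROP
        ok = np.nonzero(lls >= thr)[0]
        i0, i1 = int(ok[0]), int(ok[-1])

        def cross(inner: int, outer: int) -> float:
            f = (thr - lls[outer]) / (lls[inner] - lls[outer])
            return float(np.exp(np.log(ms[outer])
                                + f * (np.log(ms[inner]) - np.log(ms[outer]))))

        lo = float(ms[i0]) if i0 == 0 else cross(i0, i0 - 1)
        hi = float(ms[i1]) if i1 == len(ms) - 1 else cross(i1, i1 + 1)
        return (lo, hi)

    ci1, ci2 = ci(prof1), ci(prof2)
    flat = ci1 == (float(means[0]), float(means[-1])) and \
        ci2 == (float(means[0]), float(means[-1]))
    if flat:
        warnings.warn("mixture likelihood is flat over the whole grid",
                      RuntimeWarning)
    return MixtureFit(alpha=alpha_hat, m1=int(means[imax]),
                      m2=int(means[jmax]), loglik=lmax,
                      ci_m1=ci1, ci_m2=ci2,
                      profile_m1=prof1, profile_m2=prof2, flat=flat)


def tail_fraction(model: TractLengthModel, x_bp: float,
                  weight: str = "tracts", truncated: bool = True) -> float:
    """Module-level alias for :meth:`TractLengthModel.tail_fraction`."""
    return model.tail_fraction(x_bp, weight=weight, truncated=truncated)


def multi_tract_tail_prob(mean_bp: float, x_bp: float, n_tracts: int,
                          n_exceed: int) -> float:
    """P(at least n_exceed of n_tracts exceed x_bp) for a geometric model.

    Uses the nontruncated geometric survival p = (1 - 1/mean)^x and a
    log-space binomial tail so that astronomically small values stay finite.
    """
    if mean_bp <= 1:
        raise ModelError("mean_bp must be > 1")
    if n_exceed <= 0:
        return 1.0
    log_p = x_bp * math.log1p(-1.0 / mean_bp)
    p = math.exp(log_p)
    ks = np.arange(n_exceed, min(n_tracts, n_exceed + 200) + 1)
    if ks.size == 0:
        return 0.0
    log_terms = binom.logpmf(ks, n_tracts, p)
    return float(np.exp(logsumexp(log_terms)))
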