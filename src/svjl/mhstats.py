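"""Theoretical null and enrichment test for junction microhomology.

Under the null, the two sequences flanking a junction are independent with
per-base match probability ``p = sum_x f_x**2`` (composition-matched).  The
microhomology length M — the slide interval of the breakpoint — is the sum
of two independent geometric extensions, giving the closed form

    P(M = m) = (m + 1) * p**m * (1 - p)**2,   m = 0, 1, 2, ...

With uniform composition ``p = 1/4`` and ``P(M >= 1) = 7/16``.  Observed
junction spectra are compared to this null with a chi-square goodness-of-fit
test over bins {0, 1, ..., K-1, >=K}, with K chosen by the Cochran rule
(every expected count >= 1 and at least 80% of bins >= 5).  Insertion-class
junctions are excluded: an inserted sequence and a microhomology are
mutually exclusive junction patterns.

The null is pluggable: any object with ``pmf(m)`` and ``tail(k)`` can stand
in for :class:`MHNull` if a different theoretical construction is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seq import match_probability


@dataclass
class MHNull:
    """Closed-form null distribution of junction microhomology length."""

    p: float

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError("per-base match probability must be in (0, 1)")

    def pmf(self, m) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        q = 1 - self.p
        return (m + 1) * self.p ** m * q * q

    def tail(self, k: int) -> float:
        """P(M >= k)."""
        q = 1 - self.p
        return float((k + 1) * self.p ** k * q + self.p ** (k + 1))

    def binned(self, K: int) -> np.ndarray:
        """Probabilities for bins 0, 1, ..., K-1, >=K (sums to 1)."""
        probs = np.append(self.pmf(np.arange(K)), self.tail(K))
        assert abs(probs.sum() - 1) < 1e-12
        return probs


def null_pmf(base_frequencies, max_m: int = 28) -> MHNull:
    """Microhomology null from base composition.

    ``max_m`` is kept for reporting symmetry (histograms are pooled above
    it); the null itself has unbounded support.
    """
    f = np.asarray(base_frequencies, dtype=float)
    if abs(f.sum() - 1) > 1e-9 or np.any(f < 0):
        raise ValueError("base frequencies must be a probability vector")
    if np.any(f >= 1):
        raise ValueError("degenerate composition (a single base)")
    null = MHNull(match_probability(f))
    null.max_m = max_m
    return null


@dataclass
class ChisqResult:
    chi2: float
    df: int
    p_value: float
    K: int
    table: pd.DataFrame  # bin, observed, expected


def _choose_K(n: int, null: MHNull, max_K: int) -> int:
    """Largest K satisfying the Cochran rule for n observations."""
    for K in range(max_K, 0, -1):
        exp = n * null.binned(K)
        if exp.min() >= 1 and np.mean(exp >= 5) >= 0.8:
            return K
    return 1


def mh_chisq(observed, null: MHNull, K: int | None = None,
             max_K: int = 28) -> ChisqResult:
    """Chi-square goodness of fit of observed microhomology lengths.

    ``observed`` is a sequence of non-negative microhomology lengths
    (insertion-class junctions must already be excluded).  Bins are
    {0, ..., K-1, >=K}; df = K.
    """
    obs = np.asarray(list(observed), dtype=int)
    if obs.size == 0:
        raise ValueError("empty observation list")
    if np.any(obs < 0):
        raise ValueError("negative microhomology length")
    n = obs.size
    if K is None:
        K = _choose_K(n, null, max_K)
    counts = np.append(np.bincount(np.minimum(obs, K), minlength=K + 1)[:K],
                       np.sum(obs >= K))
    expected = n * null.binned(K)
    chi2, p = stats.chisquare(counts, expected)
    labels = [str(m) for m in range(K)] + [f">={K}"]
    table = pd.DataFrame({"bin": labels, "observed": counts,
                          "expected": expected})
    return ChisqResult(float(chi2), K, float(p), K, table)


def junction_pattern(call) -> str:
    """Table-3-style pattern of a junction call."""
    if call.mh_len >= 1:
        return "microhomology"
    if call.insertion_seq:
        return "insertion"
    return "blunt"


@dataclass
class MHReport:
    histogram: pd.DataFrame          # stratum, m, observed, expected
    tests: dict                      # stratum -> ChisqResult
    totals: pd.DataFrame             # sample x pattern counts


def stratified_report(calls, null: MHNull, max_m: int = 28) -> MHReport:
    """Observed-vs-theoretical microhomology report per chromothripsis
    stratum, plus per-sample pattern totals.

    Every call must carry a ``sample`` label; calls are stratified on their
    ``chromothripsis`` flag.  Insertion-class junctions contribute to the
    totals but are excluded from the microhomology histograms and tests.
    """
    for c in calls:
        if not c.sample:
            raise ValueError(f"call {c.junction_id} has no sample label")
    strata = {"chromothripsis": [], "non_chromothripsis": []}
    rows = []
    for c in calls:
        pat = junction_pattern(c)
        rows.append({"sample": c.sample, "pattern": pat})
        if pat != "insertion":
            key = "chromothripsis" if c.chromothripsis else "non_chromothripsis"
            strata[key].append(c.mh_len)

    totals = (pd.DataFrame(rows)
              .groupby(["sample", "pattern"]).size().unstack(fill_value=0)
              .reindex(columns=["microhomology", "blunt", "insertion"],
                       fill_value=0).reset_index())

    tests, hist_rows = {}, []
    for name, lens in strata.items():
        if not lens:
            continue
        res = mh_chisq(lens, null, max_K=max_m)
        tests[name] = res
        for _, r in res.table.iterrows():
            hist_rows.append({"stratum": name, "m": r["bin"],
                              "observed": int(r["observed"]),
                              "expected": float(r["expected"])})
    return MHReport(pd.DataFrame(hist_rows), tests, totals)
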