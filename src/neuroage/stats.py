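"""Nonparametric statistics battery for the longitudinal two-arm comparison.

Within-group pre/post changes use the Wilcoxon signed-rank test, between-group
comparisons the Mann–Whitney U test, categorical proportions the Pearson
chi-square, and duration associations the Pearson correlation.  The rank
tests are implemented here with the conventions used in the study reports:

* signed-rank: zero differences dropped (Wilcoxon's convention; Pratt behind
  a flag), tied |d| mid-ranked, exact two-sided p by full enumeration of the
  2^n sign assignments for n ≤ 12, otherwise a tie-corrected normal
  approximation; z is reported from min(T⁺, T⁻), hence always ≤ 0, with the
  effect direction carried in ``method_notes``;
* rank-sum: U from rank sums with mid-ranks, exact enumeration of all
  C(n1+n2, n1) group assignments for n1+n2 ≤ 12, else tie-corrected normal
  approximation; z is signed by (U − n1·n2/2) so swapping the groups flips
  its sign.

p-values are two-sided and reported uncorrected for multiplicity by default;
an optional Bonferroni/Holm adjustment can be switched on.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st

from .errors import DegenerateTableError, UndefinedTestError

logger = logging.getLogger(__name__)

EXACT_CUTOFF = 12


@dataclass
class TestResult:
    """One statistical comparison: statistic, z (where defined), two-sided p."""

    name: str
    statistic: float
    z_value: float | None
    p_value: float
    n: object  # int or (n1, n2)
    method_notes: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "z_value": self.z_value,
            "p_value": self.p_value,
            "n": self.n,
            "method_notes": self.method_notes,
        }


def _tie_term(ranked_values: np.ndarray) -> float:
    """Σ(t³ − t) over groups of tied values."""
    _, counts = np.unique(ranked_values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def wilcoxon_signed_rank(
    x,
    y=None,
    zero_method: str = "drop",
    exact_cutoff: int = EXACT_CUTOFF,
    mode: str = "auto",
) -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    ``x`` may be the differences directly, or paired with ``y`` (d = x − y).
    ``mode``: "auto" (exact for n ≤ ``exact_cutoff``), "exact", or "approx".
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    n_zero = int(np.sum(d == 0))
    if zero_method == "drop":
        d_nz = d[d != 0]
        if d_nz.size == 0:
            raise UndefinedTestError("all paired differences are zero")
        ranks = st.rankdata(np.abs(d_nz))
    elif zero_method == "pratt":
        if np.all(d == 0):
            raise UndefinedTestError("all paired differences are zero")
        ranks_all = st.rankdata(np.abs(d))
        d_nz = d[d != 0]
        ranks = ranks_all[d != 0]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n = d_nz.size
    t_plus = float(ranks[d_nz > 0].sum())
    t_minus = float(ranks[d_nz < 0].sum())
    t_min = min(t_plus, t_minus)
    direction = "positive" if t_plus > t_minus else ("negative" if t_minus > t_plus else "none")

    mu = ranks.sum() / 2.0
    var = float(np.sum(ranks ** 2)) / 4.0  # equals n(n+1)(2n+1)/24 − Σ(t³−t)/48 untied/tied
    sd = np.sqrt(var)
    z = (t_min - mu) / sd if sd > 0 else 0.0

    exact = mode == "exact" or (mode == "auto" and n <= exact_cutoff)
    if exact:
        # enumerate all 2^n sign assignments over the realized ranks
        tp = np.zeros(1)
        for r in ranks:
            tp = np.concatenate([tp, tp + r])
        p_le = np.mean(tp <= t_plus + 1e-12)
        p_ge = np.mean(tp >= t_plus - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        notes = f"exact enumeration (2^{n}); zeros dropped: {n_zero}; direction: {direction}"
    else:
        if sd == 0:
            raise UndefinedTestError("zero variance in signed-rank approximation")
        p = min(1.0, 2.0 * st.norm.cdf(z))
        notes = f"normal approximation, tie-corrected; zeros dropped: {n_zero}; direction: {direction}"
    if zero_method == "pratt":
        notes += "; Pratt zero handling"
    return TestResult(
        name="wilcoxon_signed_rank",
        statistic=t_min,
        z_value=float(z),
        p_value=float(p),
        n=n,
        method_notes=notes,
    )


def mann_whitney_u(x, y, exact_cutoff: int = EXACT_CUTOFF, mode: str = "auto") -> TestResult:
    """Mann–Whitney U test (two-sided) with mid-ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise UndefinedTestError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = st.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1))) if n > 1 else 0.0
    sd = np.sqrt(var)
    z = (u1 - mu) / sd if sd > 0 else 0.0

    exact = mode == "exact" or (mode == "auto" and n <= exact_cutoff)
    if exact:
        rank_sum_base = n1 * (n1 + 1) / 2.0
        us = np.fromiter(
            (sum(c) - rank_sum_base for c in itertools.combinations(ranks, n1)),
            dtype=float,
        )
        p_le = np.mean(us <= u1 + 1e-12)
        p_ge = np.mean(us >= u1 - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        notes = f"exact enumeration C({n},{n1})"
    else:
        if sd == 0:
            p, z = 1.0, 0.0
            notes = "degenerate: all pooled values tied"
        else:
            p = min(1.0, 2.0 * st.norm.sf(abs(z)))
            notes = "normal approximation, tie-corrected"
    return TestResult(
        name="mann_whitney_u",
        statistic=float(u1),
        z_value=float(z),
        p_value=float(p),
        n=(n1, n2),
        method_notes=notes,
    )


def chi_square(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2×k contingency table (no continuity correction
    by default)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2×k contingency table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTableError("zero marginal in contingency table")
    res = st.chi2_contingency(table, correction=correction)
    return TestResult(
        name="chi_square",
        statistic=float(res.statistic),
        z_value=None,
        p_value=float(res.pvalue),
        n=int(table.sum()),
        method_notes=f"df={res.dof}; continuity correction: {correction}",
    )


def pearson_r(x, y) -> TestResult:
    """Pearson product-moment correlation, two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedTestError("zero variance in correlation input")
    res = st.pearsonr(x, y)
    return TestResult(
        name="pearson_r",
        statistic=float(res.statistic),
        z_value=None,
        p_value=float(res.pvalue),
        n=int(x.size),
        method_notes="two-sided t transform, df=n-2",
    )


# ---------------------------------------------------------------------------
# cohort-level battery


def stratify(cohort: pd.DataFrame, by: str) -> dict:
    """Partition a wide cohort table by sex, baseline gap sign, or arm.

    A baseline gap of exactly 0 goes to the "younger" stratum (BBA ≤ CA),
    with a log note.
    """
    if by == "sex":
        return {s: g for s, g in cohort.groupby("sex")}
    if by == "arm":
        return {s: g for s, g in cohort.groupby("arm")}
    if by == "baseline_gap_sign":
        gap = cohort["gap_pre"]
        n_tied = int((gap == 0).sum())
        if n_tied:
            logger.info("%d subjects with baseline gap exactly 0 assigned to 'younger'", n_tied)
        lab = np.where(gap > 0, "older", "younger")
        return {s: g for s, g in cohort.groupby(lab)}
    raise ValueError(f"unknown stratifier {by!r}")


@dataclass
class AnalysisBattery:
    """Ordered collection of (comparison id, stratum, TestResult)."""

    results: list = field(default_factory=list)
    correction: str | None = None

    def add(self, comparison: str, stratum: str, result: TestResult):
        self.results.append((comparison, stratum, result))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp, stratum, r in self.results:
            d = r.to_dict()
            d["comparison"] = comp
            d["stratum"] = stratum
            if isinstance(d["n"], tuple):
                d["n"] = "/".join(str(v) for v in d["n"])
            rows.append(d)
        frame = pd.DataFrame(
            rows,
            columns=["comparison", "stratum", "name", "statistic", "z_value", "p_value", "n",
                     "method_notes"],
        )
        if self.correction:
            from statsmodels.stats.multitest import multipletests

            frame["p_adjusted"] = multipletests(frame["p_value"], method=self.correction)[1]
        return frame

    def to_json(self, path=None) -> str:
        s = self.to_frame().to_json(orient="records", indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _wide_required(cohort: pd.DataFrame):
    required = {"subject_id", "arm", "sex", "ca_pre", "ca_post", "bba_pre", "bba_post",
                "br_pre", "br_post", "gap_pre", "gap_post", "followup_months"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    complete = cohort.dropna(subset=sorted(required - {"subject_id", "arm", "sex"}))
    n_dropped = len(cohort) - len(complete)
    if n_dropped:
        logger.info("excluding %d subjects with incomplete visits from the battery", n_dropped)
    return complete


def run_battery(cohort: pd.DataFrame, correction: str | None = None) -> AnalysisBattery:
    """Run the full comparison matrix on a wide (one row per subject) table.

    Within-arm signed-rank tests (BBA pre vs post, BR pre vs post, BBA vs CA
    at each visit), between-arm rank-sum tests (ΔBBA, Δgap, ΔCA, gap at each
    visit), the same ΔBBA/ΔCA contrasts restricted to sex and baseline-gap
    strata, per-arm Pearson correlation of ΔBBA with intervention duration,
    and chi-square on the symptom indicator pre vs post.  p-values are
    uncorrected unless ``correction`` is given ("bonferroni", "holm", ...).
    """
    cohort = _wide_required(cohort)
    battery = AnalysisBattery(correction=correction)
    arms = list(dict.fromkeys(cohort["arm"]))

    def safe(comparison, stratum, fn):
        try:
            battery.add(comparison, stratum, fn())
        except (UndefinedTestError, DegenerateTableError, ValueError) as exc:
            logger.warning("skipping %s [%s]: %s", comparison, stratum, exc)

    for arm in arms:
        g = cohort[cohort["arm"] == arm]
        safe("bba_pre_vs_post", arm, lambda g=g: wilcoxon_signed_rank(g["bba_post"], g["bba_pre"]))
        safe("br_pre_vs_post", arm, lambda g=g: wilcoxon_signed_rank(g["br_post"], g["br_pre"]))
        safe("bba_vs_ca_pre", arm, lambda g=g: wilcoxon_signed_rank(g["bba_pre"], g["ca_pre"]))
        safe("bba_vs_ca_post", arm, lambda g=g: wilcoxon_signed_rank(g["bba_post"], g["ca_post"]))

    if len(arms) >= 2:
        a, b = arms[0], arms[1]
        ga, gb = cohort[cohort["arm"] == a], cohort[cohort["arm"] == b]

        def deltas(g):
            return {
                "bba": g["bba_post"] - g["bba_pre"],
                "gap": g["gap_post"] - g["gap_pre"],
                "ca": g["ca_post"] - g["ca_pre"],
            }

        da, db = deltas(ga), deltas(gb)
        for q in ("bba", "gap", "ca"):
            safe(f"delta_{q}_between_arms", "all",
                 lambda q=q: mann_whitney_u(da[q], db[q]))
        safe("gap_pre_between_arms", "all",
             lambda: mann_whitney_u(ga["gap_pre"], gb["gap_pre"]))
        safe("gap_post_between_arms", "all",
             lambda: mann_whitney_u(ga["gap_post"], gb["gap_post"]))

        for by in ("sex", "baseline_gap_sign"):
            for stratum, sub in sorted(stratify(cohort, by).items()):
                sa = sub[sub["arm"] == a]
                sb = sub[sub["arm"] == b]
                if len(sa) == 0 or len(sb) == 0:
                    logger.warning("empty stratum %s=%s in one arm; tests skipped", by, stratum)
                    continue
                dsa, dsb = deltas(sa), deltas(sb)
                for q in ("bba", "ca"):
                    safe(f"delta_{q}_between_arms", f"{by}={stratum}",
                         lambda q=q, dsa=dsa, dsb=dsb: mann_whitney_u(dsa[q], dsb[q]))

        if "sex" in cohort.columns:
            f_counts = [int((g["sex"] == "F").sum()) for g in (ga, gb)]
            m_counts = [int((g["sex"] == "M").sum()) for g in (ga, gb)]
            safe("sex_between_arms", "all",
                 lambda: chi_square([[f_counts[0], m_counts[0]], [f_counts[1], m_counts[1]]]))

    for arm in arms:
        g = cohort[cohort["arm"] == arm]
        safe("delta_bba_vs_duration", arm,
             lambda g=g: pearson_r(g["followup_months"], g["bba_post"] - g["bba_pre"]))
        if {"symptom_pre", "symptom_post"} <= set(g.columns):
            pre_y = int(g["symptom_pre"].sum())
            post_y = int(g["symptom_post"].sum())
            n = len(g)
            safe("symptom_pre_vs_post", arm,
                 lambda pre_y=pre_y, post_y=post_y, n=n: chi_square(
                     [[pre_y, n - pre_y], [post_y, n - post_y]]))
    return battery


def group_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean (sd) summary of CA, BBA, gap and BR at both visits."""
    cohort = _wide_required(cohort)
    rows = []
    for arm, g in cohort.groupby("arm"):
        row = {"arm": arm, "n": len(g), "pct_female": 100.0 * (g["sex"] == "F").mean()}
        for q in ("ca", "bba", "gap", "br"):
            for v in ("pre", "post"):
                col = f"{q}_{v}"
                row[f"{col}_mean"] = g[col].mean()
                row[f"{col}_sd"] = g[col].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)
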