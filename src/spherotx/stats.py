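"""Fixed-effects inference layer: ANOVA, Tukey HSD, Student's t-test.

Sums of squares, the pooled t statistic and the Tukey studentized-range
statistic are computed here from their textbook formulas; tail probabilities
come from scipy's F, t and studentized-range distributions.

Conventions
-----------
* One-way ANOVA: F = MS_between / MS_within with df (k-1, N-k).
* Two-way ANOVA: balanced complete designs only, with interaction; in a
  balanced design all sums-of-squares types coincide, so no type choice
  arises.
* Tukey HSD: q_ij = |m_i - m_j| / sqrt(MS_w/2 * (1/n_i + 1/n_j))
  (Tukey-Kramer for unequal n), adjusted p from the studentized range with
  (k, residual df).
* t-test: Student's pooled equal-variance t by default; Welch behind a flag.

Degenerate inputs (zero variance everywhere) yield statistics reported as
missing (NaN) with a diagnostic, never a fabricated p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value to the star notation * <0.05 ** <0.01 *** <0.001 **** <0.0001."""
    if not np.isfinite(p):
        return ""
    for cut, stars in _STAR_LEVELS:
        if p < cut:
            return stars
    return "ns"


@dataclass
class AnovaTerm:
    name: str
    ss: float
    df: int
    ms: float
    F: Optional[float]
    p: Optional[float]


@dataclass
class AnovaResult:
    """ANOVA decomposition with one row per model term plus the residual."""

    terms: List[AnovaTerm]
    residual_ss: float
    residual_df: int
    residual_ms: float
    total_ss: float
    alpha: float = 0.05
    diagnostics: List[str] = field(default_factory=list)

    def term(self, name: str) -> AnovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "terms": [
                {
                    "name": t.name,
                    "ss": t.ss,
                    "df": t.df,
                    "ms": t.ms,
                    "F": t.F,
                    "p": t.p,
                    "stars": significance_stars(t.p) if t.p is not None else "",
                }
                for t in self.terms
            ],
            "residual": {
                "ss": self.residual_ss,
                "df": self.residual_df,
                "ms": self.residual_ms,
            },
            "total_ss": self.total_ss,
            "alpha": self.alpha,
            "diagnostics": list(self.diagnostics),
        }


@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float
    q: float
    p_adj: float
    significant: bool


@dataclass
class TukeyResult:
    pairs: List[TukeyPair]
    k: int
    residual_df: int
    ms_within: float
    alpha: float

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "residual_df": self.residual_df,
            "ms_within": self.ms_within,
            "alpha": self.alpha,
            "pairs": [
                {
                    "pair": f"{p.group_a} vs {p.group_b}",
                    "mean_diff": p.mean_diff,
                    "q": p.q,
                    "p_adj": p.p_adj,
                    "significant": p.significant,
                    "stars": significance_stars(p.p_adj),
                }
                for p in self.pairs
            ],
        }


def _as_clean_arrays(groups: Mapping[str, Sequence[float]]) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        a = np.asarray(vals, dtype=float)
        if a.ndim != 1:
            raise ValueError(f"group {name!r}: expected a 1-D sample")
        if a.size < 2:
            raise ValueError(f"group {name!r}: needs >= 2 observations, got {a.size}")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {name!r}: non-finite values present")
        out[str(name)] = a
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Parameters
    ----------
    groups:
        Mapping of group label to its sample (each >= 2 finite observations;
        >= 2 groups).

    Returns
    -------
    AnovaResult with a single "group" term.  If both between- and
    within-group variance are zero the F statistic is undefined and reported
    as NaN with a diagnostic.
    """
    g = _as_clean_arrays(groups)
    if len(g) < 2:
        raise ValueError(f"need >= 2 groups, got {len(g)}")
    all_vals = np.concatenate(list(g.values()))
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(g)

    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in g.values())
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in g.values())
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w

    diagnostics: List[str] = []
    if ms_w == 0.0 and ms_b == 0.0:
        F = p = float("nan")
        diagnostics.append("zero variance within and between groups: F undefined")
    elif ms_w == 0.0:
        F, p = float("inf"), 0.0
        diagnostics.append("zero within-group variance: F infinite")
    else:
        F = ms_b / ms_w
        p = float(sps.f.sf(F, df_b, df_w))

    return AnovaResult(
        terms=[AnovaTerm("group", ss_between, df_b, ms_b, F, p)],
        residual_ss=ss_within,
        residual_df=df_w,
        residual_ms=ms_w,
        total_ss=ss_between + ss_within,
        alpha=alpha,
        diagnostics=diagnostics,
    )


def two_way_anova(
    records: Sequence[Tuple[str, str, float]], alpha: float = 0.05
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction, balanced designs only.

    Parameters
    ----------
    records:
        Iterable of ``(level_a, level_b, value)`` tuples covering a complete
        factorial design with an equal number of replicates per cell.

    Raises
    ------
    ValueError
        If the design is incomplete or unbalanced (use the one-way path for
        such data).
    """
    if not records:
        raise ValueError("empty data")
    a_levels = sorted({str(r[0]) for r in records})
    b_levels = sorted({str(r[1]) for r in records})
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("each factor needs >= 2 levels")

    cells: Dict[Tuple[str, str], List[float]] = {
        (a, b): [] for a in a_levels for b in b_levels
    }
    for a, b, v in records:
        v = float(v)
        if not math.isfinite(v):
            raise ValueError("non-finite value in data")
        cells[(str(a), str(b))].append(v)
    counts = {key: len(vals) for key, vals in cells.items()}
    n_rep = counts[(a_levels[0], b_levels[0])]
    if n_rep < 1 or len(set(counts.values())) != 1:
        raise ValueError(
            "unbalanced or incomplete design (unequal cell counts); "
            "analyze factors separately with one_way_anova"
        )

    arr = np.array(
        [[cells[(a, b)] for b in b_levels] for a in a_levels], dtype=float
    )  # (A, B, n_rep)
    A, B = len(a_levels), len(b_levels)
    grand = arr.mean()
    mean_a = arr.mean(axis=(1, 2))
    mean_b = arr.mean(axis=(0, 2))
    mean_cell = arr.mean(axis=2)

    ss_a = B * n_rep * float(np.sum((mean_a - grand) ** 2))
    ss_b = A * n_rep * float(np.sum((mean_b - grand) ** 2))
    ss_ab = n_rep * float(
        np.sum((mean_cell - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    )
    ss_res = float(np.sum((arr - mean_cell[..., None]) ** 2))
    ss_tot = float(np.sum((arr - grand) ** 2))

    df_a, df_b = A - 1, B - 1
    df_ab = df_a * df_b
    df_res = A * B * (n_rep - 1)

    diagnostics: List[str] = []
    terms: List[AnovaTerm] = []
    if df_res == 0:
        diagnostics.append("one replicate per cell: no residual df, p-values undefined")
    ms_res = ss_res / df_res if df_res > 0 else float("nan")
    for name, ss, df in (
        ("factor_a", ss_a, df_a),
        ("factor_b", ss_b, df_b),
        ("interaction", ss_ab, df_ab),
    ):
        ms = ss / df
        if df_res == 0 or not math.isfinite(ms_res):
            F = p = None
        elif ms_res == 0.0:
            F, p = (float("inf"), 0.0) if ms > 0 else (float("nan"), float("nan"))
            if ms == 0:
                diagnostics.append(f"{name}: zero MS with zero residual MS, F undefined")
        else:
            F = ms / ms_res
            p = float(sps.f.sf(F, df, df_res))
        terms.append(AnovaTerm(name, ss, df, ms, F, p))

    return AnovaResult(
        terms=terms,
        residual_ss=ss_res,
        residual_df=df_res,
        residual_ms=ms_res,
        total_ss=ss_tot,
        alpha=alpha,
        diagnostics=diagnostics,
    )


def tukey_critical_value(alpha: float, k: int, df: int) -> float:
    """Upper-alpha quantile of the studentized range with k groups and df."""
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_hsd(
    groups: Mapping[str, Sequence[float]],
    residual_df: Optional[int] = None,
    ms_within: Optional[float] = None,
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey's HSD all-pairs comparison after a one-way ANOVA.

    ``residual_df`` and ``ms_within`` default to the one-way ANOVA values
    computed from ``groups`` themselves; pass them explicitly to reuse a
    previously fitted ANOVA.
    """
    g = _as_clean_arrays(groups)
    k = len(g)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if ms_within is None or residual_df is None:
        aov = one_way_anova(g, alpha=alpha)
        ms_within = aov.residual_ms
        residual_df = aov.residual_df
    if not ms_within > 0:
        raise ValueError(f"ms_within must be > 0, got {ms_within}")

    names = list(g)
    pairs: List[TukeyPair] = []
    for na, nb in itertools.combinations(names, 2):
        a, b = g[na], g[nb]
        diff = a.mean() - b.mean()
        se = math.sqrt(ms_within / 2.0 * (1.0 / a.size + 1.0 / b.size))
        q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, residual_df)) if q > 0 else 1.0
        p_adj = min(max(p_adj, 0.0), 1.0)
        pairs.append(TukeyPair(na, nb, diff, q, p_adj, p_adj < alpha))
    return TukeyResult(pairs=pairs, k=k, residual_df=int(residual_df),
                       ms_within=float(ms_within), alpha=alpha)


@dataclass
class TTestResult:
    statistic: float
    df: float
    p: float
    diagnostics: List[str] = field(default_factory=list)


def t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    two_tailed: bool = True,
    paired: bool = False,
    welch: bool = False,
) -> TTestResult:
    """Student's t-test (pooled equal-variance by default).

    Set ``welch=True`` for the unequal-variance Welch test, ``paired=True``
    for a paired test (equal lengths required).  Zero pooled variance with
    equal means yields a NaN statistic and missing p with a diagnostic.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values present")

    diagnostics: List[str] = []
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal sample sizes")
        d = a - b
        sd = d.std(ddof=1)
        df = float(d.size - 1)
        if sd == 0.0:
            if d.mean() == 0.0:
                diagnostics.append("zero difference variance with zero mean: t undefined")
                return TTestResult(float("nan"), df, float("nan"), diagnostics)
            return TTestResult(math.copysign(float("inf"), d.mean()), df, 0.0, diagnostics)
        t = d.mean() / (sd / math.sqrt(d.size))
    elif welch:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / a.size + vb / b.size
        if se2 == 0.0:
            diagnostics.append("zero variance in both samples: t undefined")
            return TTestResult(float("nan"), float("nan"), float("nan"), diagnostics)
        t = (a.mean() - b.mean()) / math.sqrt(se2)
        df = se2**2 / (
            (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
        )
    else:
        df = float(a.size + b.size - 2)
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        if sp2 == 0.0:
            if a.mean() == b.mean():
                diagnostics.append("zero pooled variance with equal means: t undefined")
                return TTestResult(float("nan"), df, float("nan"), diagnostics)
            return TTestResult(
                math.copysign(float("inf"), a.mean() - b.mean()), df, 0.0, diagnostics
            )
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))

    if two_tailed:
        p = 2.0 * float(sps.t.sf(abs(t), df))
    else:
        p = float(sps.t.sf(t, df))
    return TTestResult(float(t), df, min(p, 1.0), diagnostics)


def summarize(sample: Sequence[float]) -> dict:
    """Mean, SD, SEM and n for a sample (SD/SEM missing for n = 1)."""
    a = np.asarray(sample, dtype=float)
    a = a[np.isfinite(a)]
    n = int(a.size)
    if n == 0:
        return {"mean": float("nan"), "sd": float("nan"), "sem": float("nan"), "n": 0}
    sd = float(a.std(ddof=1)) if n > 1 else float("nan")
    return {
        "mean": float(a.mean()),
        "sd": sd,
        "sem": sd / math.sqrt(n) if n > 1 else float("nan"),
        "n": n,
    }


def studentized_range_mc_quantile(
    alpha: float, k: int, df: int, n_draws: int = 1_000_000, seed: int = 0
) -> float:
    """Monte-Carlo estimate of the upper-alpha studentized range quantile.

    Draws ``n_draws`` realizations of range(k standard normals) / s with
    s^2 ~ chi-square(df)/df; independent of the analytic distribution
    routine, usable as an oracle for it.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    chunk = 200_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        z = rng.standard_normal((m, k))
        rng_range = z.max(axis=1) - z.min(axis=1)
        s = np.sqrt(rng.chisquare(df, size=m) / df)
        out[done : done + m] = rng_range / s
        done += m
    return float(np.quantile(out, 1.0 - alpha))
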