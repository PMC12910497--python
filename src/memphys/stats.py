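"""Statistical layer: control normalization, two-way fixed-effects ANOVA
with interaction, and Tukey HSD post hoc comparisons.

The study design is a factorial of membrane model (3 levels) x serotonin
concentration (6 levels including the 0 mM control) with replicate
measurements per cell.  Balanced designs use the classical closed-form
sum-of-squares decomposition (cell-mean contrasts); unbalanced designs fall
back to a Type-II decomposition via OLS.  Tukey HSD p values come from the
studentized range distribution, whose CDF is evaluated here by
Gauss-Legendre quadrature so the module is self-contained and testable
against an independent oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StudyTable",
    "AnovaResult",
    "normalize_to_control",
    "two_way_anova",
    "tukey_hsd",
    "studentized_range_cdf",
    "stars",
]

#: significance stars at the thresholds used in the figure captions
STAR_THRESHOLDS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def stars(p: float) -> str:
    """Map a p value to the star annotation convention (ns above 0.05)."""
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return "ns"


@dataclass
class StudyTable:
    """Tidy replicated measurements keyed by (membrane, conc).

    ``data`` has columns membrane (str), conc (numeric), replicate (int) and
    value (float); ``units`` tags the measured quantity.
    """

    data: pd.DataFrame
    units: str = ""

    REQUIRED = ("membrane", "conc", "replicate", "value")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"StudyTable missing columns {sorted(missing)}")

    @property
    def is_balanced(self) -> bool:
        counts = self.data.groupby(["membrane", "conc"], sort=False)["value"].count()
        full = counts.index.get_level_values(0).nunique() * counts.index.get_level_values(1).nunique()
        return counts.nunique() == 1 and len(counts) == full

    def cell_counts(self) -> pd.Series:
        return self.data.groupby(["membrane", "conc"])["value"].count()

    def to_array(self) -> tuple[np.ndarray, list, list]:
        """Balanced table as an (a, b, n) array plus the factor levels."""
        mems = list(pd.unique(self.data["membrane"]))
        concs = sorted(pd.unique(self.data["conc"]))
        counts = self.cell_counts()
        if counts.nunique() != 1 or len(counts) != len(mems) * len(concs):
            raise ValueError("table is not balanced")
        n = int(counts.iloc[0])
        arr = np.empty((len(mems), len(concs), n))
        for i, m in enumerate(mems):
            for j, c in enumerate(concs):
                v = self.data.loc[
                    (self.data["membrane"] == m) & (self.data["conc"] == c), "value"
                ].to_numpy()
                arr[i, j] = v
        return arr, mems, concs


def normalize_to_control(
    values: np.ndarray | list, control_mean: float
) -> np.ndarray:
    """Divide values by the control mean, so the control maps to 1."""
    if control_mean == 0:
        raise ZeroDivisionError("control mean is zero: cannot normalize")
    return np.asarray(values, dtype=float) / control_mean


def normalize_table(tbl: StudyTable) -> pd.DataFrame:
    """Per-membrane control-normalized cell means with error bars.

    Returns columns membrane, conc, mean_rel, sd_rel.  Every value is
    divided by its membrane's control (conc == 0) mean; the control row's
    sd_rel is the relative SD of the raw control replicates prior to
    normalization, matching the reporting convention of the study design.
    """
    rows = []
    for mem, g in tbl.data.groupby("membrane", sort=False):
        ctrl = g.loc[g["conc"] == 0, "value"]
        if ctrl.empty:
            raise ValueError(f"membrane {mem!r}: no conc = 0 control")
        c_mean = float(ctrl.mean())
        for conc, gc in g.groupby("conc"):
            rel = normalize_to_control(gc["value"].to_numpy(), c_mean)
            rows.append(
                {
                    "membrane": mem,
                    "conc": conc,
                    "mean_rel": float(rel.mean()),
                    "sd_rel": float(np.std(gc["value"].to_numpy(), ddof=1) / c_mean)
                    if len(gc) > 1
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    """Two-way ANOVA decomposition: one row per effect plus the residual."""

    table: pd.DataFrame  # index: membrane, conc, interaction, residual
    mse: float
    df_resid: int
    balanced: bool

    def summary(self) -> str:
        return "Two-way ANOVA (fixed effects)\n" + self.table.to_string(
            float_format=lambda v: f"{v:.6g}"
        )

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]


def _balanced_anova_arrays(arr: np.ndarray) -> dict[str, tuple[float, int]]:
    """Closed-form fixed-effects SS decomposition for a balanced (a, b, n)
    layout.  Returns {effect: (SS, df)}."""
    a, b, n = arr.shape
    grand = arr.mean()
    mean_a = arr.mean(axis=(1, 2))
    mean_b = arr.mean(axis=(0, 2))
    mean_ab = arr.mean(axis=2)
    ss_a = b * n * float(((mean_a - grand) ** 2).sum())
    ss_b = a * n * float(((mean_b - grand) ** 2).sum())
    ss_ab = n * float(
        ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    )
    ss_res = float(((arr - mean_ab[:, :, None]) ** 2).sum())
    return {
        "membrane": (ss_a, a - 1),
        "conc": (ss_b, b - 1),
        "interaction": (ss_ab, (a - 1) * (b - 1)),
        "residual": (ss_res, a * b * (n - 1)),
    }


def two_way_anova(tbl: StudyTable) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction for membrane x conc.

    Balanced tables use the classical SS decomposition (which sums exactly
    to the total SS); unbalanced tables use Type-II sums of squares via OLS
    and emit a warning.  Requires >= 2 replicates per cell.
    """
    counts = tbl.cell_counts()
    if (counts < 2).any():
        raise ValueError("every (membrane, conc) cell needs >= 2 replicates")

    if tbl.is_balanced:
        arr, _, _ = tbl.to_array()
        parts = _balanced_anova_arrays(arr)
        balanced = True
    else:
        warnings.warn(
            "unbalanced design: using Type-II sums of squares", UserWarning
        )
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        d = tbl.data.rename(columns={"membrane": "mem"})
        model = smf.ols("value ~ C(mem) * C(conc)", data=d).fit()
        at = anova_lm(model, typ=2)
        parts = {
            "membrane": (float(at.loc["C(mem)", "sum_sq"]), int(at.loc["C(mem)", "df"])),
            "conc": (float(at.loc["C(conc)", "sum_sq"]), int(at.loc["C(conc)", "df"])),
            "interaction": (
                float(at.loc["C(mem):C(conc)", "sum_sq"]),
                int(at.loc["C(mem):C(conc)", "df"]),
            ),
            "residual": (
                float(at.loc["Residual", "sum_sq"]),
                int(at.loc["Residual", "df"]),
            ),
        }
        balanced = False

    ss_res, df_res = parts["residual"]
    mse = ss_res / df_res if df_res > 0 else float("nan")
    rows = []
    for eff in ("membrane", "conc", "interaction"):
        ss, df = parts[eff]
        ms = ss / df if df else float("nan")
        F = ms / mse if mse > 0 else (0.0 if ss == 0 else float("inf"))
        p = float(sps.f.sf(F, df, df_res)) if np.isfinite(F) else 0.0
        rows.append({"effect": eff, "sum_sq": ss, "df": df, "F": F, "p": p})
    rows.append(
        {"effect": "residual", "sum_sq": ss_res, "df": df_res, "F": np.nan, "p": np.nan}
    )
    table = pd.DataFrame(rows).set_index("effect")
    return AnovaResult(table=table, mse=mse, df_resid=df_res, balanced=balanced)


# ---------------------------------------------------------------------------
# studentized range distribution by quadrature


def _phi(z):
    return np.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)


def _Phi(z):
    return sps.norm.cdf(z)


def _srange_cdf_given_s(q: float, k: int, z_nodes, z_weights) -> float:
    """P(range of k iid N(0,1) <= q): k * int phi(z) [Phi(z) - Phi(z-q)]^(k-1) dz."""
    z = z_nodes
    inner = _phi(z) * (_Phi(z) - _Phi(z - q)) ** (k - 1)
    return float(k * np.sum(z_weights * inner))


def studentized_range_cdf(q: float, k: int, df: float, n_quad: int = 64) -> float:
    """CDF of the studentized range Q(k, df) at q, by nested Gauss-Legendre
    quadrature over the scale variable s ~ sqrt(chi2_df / df) and the
    normal-range integral.

    For df = inf the scale integral collapses to the plain normal-range CDF.
    """
    if q <= 0:
        return 0.0
    if k < 2:
        raise ValueError("studentized range needs k >= 2 groups")

    zn, zw = np.polynomial.legendre.leggauss(n_quad)
    # the inner integrand lives where phi(z) is appreciable: z in [-9, 9+q]
    def inner(qs: float) -> float:
        lo, hi = -9.0, 9.0 + qs
        z = 0.5 * (hi - lo) * zn + 0.5 * (hi + lo)
        w = 0.5 * (hi - lo) * zw
        return _srange_cdf_given_s(qs, k, z, w)

    if not np.isfinite(df):
        return inner(q)

    # density of S = sqrt(chi2_df/df); integrate s over its effective support
    sd = 1.0 / math.sqrt(2.0 * df)
    s_lo = max(1e-9, 1.0 - 10 * sd)
    s_hi = 1.0 + 12 * sd
    if df < 20:  # wide, skewed density at small df
        s_lo, s_hi = 1e-9, 1.0 + 14.0 / math.sqrt(df)
    sn, sw = np.polynomial.legendre.leggauss(n_quad)
    s = 0.5 * (s_hi - s_lo) * sn + 0.5 * (s_hi + s_lo)
    w = 0.5 * (s_hi - s_lo) * sw
    # f_S(s) = 2 (df/2)^(df/2) / Gamma(df/2) s^(df-1) exp(-df s^2 / 2)
    logf = (
        math.log(2.0)
        + 0.5 * df * math.log(0.5 * df)
        - math.lgamma(0.5 * df)
        + (df - 1.0) * np.log(s)
        - 0.5 * df * s * s
    )
    fs = np.exp(logf)
    vals = np.array([inner(q * si) for si in s])
    return float(np.clip(np.sum(w * fs * vals), 0.0, 1.0))


def tukey_hsd(
    tbl: StudyTable,
    within: str = "conc-within-membrane",
    mse: float | None = None,
    df_resid: int | None = None,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons inside each family.

    ``within="conc-within-membrane"`` compares concentration levels inside
    each membrane model; ``"membrane-within-conc"`` compares membranes at
    each concentration.  The pooled residual mean square from the two-way
    ANOVA is used unless ``mse``/``df_resid`` are given.  Unequal group
    sizes use the Tukey-Kramer statistic.  Returns a tidy frame with q,
    p and star annotations.
    """
    if within == "conc-within-membrane":
        family_col, group_col = "membrane", "conc"
    elif within == "membrane-within-conc":
        family_col, group_col = "conc", "membrane"
    else:
        raise ValueError(f"unknown family {within!r}")

    if mse is None or df_resid is None:
        res = two_way_anova(tbl)
        mse, df_resid = res.mse, res.df_resid

    rows = []
    for fam, g in tbl.data.groupby(family_col, sort=False):
        groups = g.groupby(group_col)["value"]
        means = groups.mean()
        ns = groups.count()
        levels = list(means.index)
        k = len(levels)
        if k < 2:
            raise ValueError(f"family {fam!r} has fewer than 2 groups")
        for i in range(k):
            for j in range(i + 1, k):
                a, b = levels[i], levels[j]
                diff = float(means[b] - means[a])
                se = math.sqrt(0.5 * mse * (1.0 / ns[a] + 1.0 / ns[b]))
                q = abs(diff) / se if se > 0 else float("inf")
                p = 1.0 - studentized_range_cdf(q, k, df_resid)
                rows.append(
                    {
                        family_col: fam,
                        "group1": a,
                        "group2": b,
                        "diff": diff,
                        "q": q,
                        "p": p,
                        "stars": stars(p),
                    }
                )
    return pd.DataFrame(rows)
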