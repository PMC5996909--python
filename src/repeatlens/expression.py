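"""Dual-luciferase normalization and per-motif expression-effect estimation.

Reporter constructs carry repeat alleles upstream of a minimal promoter;
firefly luminescence is normalized by co-transfected Renilla, and relative
activity is expressed on a 0-100% scale anchored at the negative and
positive controls:

    percent = 100 * (ratio_construct - ratio_neg) / (ratio_pos - ratio_neg)

Two estimators of the per-motif effect are provided.  ``per_motif_effect``
reproduces the published pairwise arithmetic: the activity difference
between two constructs of comparable composition divided by the *total*
number of motifs added, attributed to the dominant added motif type (e.g.
4- vs 10-repeat: 2.76% / 6 motifs = 0.46% per CACA20; 12- vs 16-repeat:
5.84% / 4 = 1.46% per CGCA20).  ``MotifActivityModel`` is the principled
alternative: an ordinary least-squares fit of percent on the per-type motif
counts, which attributes the change per added motif of each type jointly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, UsageError
from .motif_core import DEFAULT_ALPHABET, AlleleStructure, parse_nomenclature

NEGATIVE = "NEGATIVE"
POSITIVE = "POSITIVE"
CONTROL_IDS = (NEGATIVE, POSITIVE)


@dataclass(frozen=True)
class RelativeActivity:
    construct_id: str
    percent: float
    se: float
    n: int


def relative_activity(wells: pd.DataFrame) -> list[RelativeActivity]:
    """Normalize a plate of wells to percent relative luciferase activity.

    ``wells`` needs columns construct_id, replicate, firefly, renilla and at
    least one NEGATIVE and one POSITIVE control well.  Ratios are
    firefly/renilla per well, averaged per construct before anchoring on the
    control means; the SE is propagated from the replicate variance of the
    experimental ratios with the controls treated as fixed.
    """
    required = {"construct_id", "firefly", "renilla"}
    if not required.issubset(wells.columns):
        raise UsageError(f"plate table must have columns {sorted(required)}")
    if (wells["renilla"] <= 0).any():
        raise UsageError("renilla luminescence must be positive in every well")
    df = wells.copy()
    df["ratio"] = df["firefly"] / df["renilla"]
    groups = df.groupby("construct_id")["ratio"]
    means = groups.mean()
    if NEGATIVE not in means.index or POSITIVE not in means.index:
        raise UsageError("plate must contain NEGATIVE and POSITIVE control wells")
    neg, pos = means[NEGATIVE], means[POSITIVE]
    span = pos - neg
    if span <= 0:
        raise UsageError(
            f"degenerate normalization: positive control ratio ({pos:.4g}) "
            f"<= negative ({neg:.4g})"
        )
    out = []
    for cid, grp in df.groupby("construct_id", sort=False):
        if cid in CONTROL_IDS:
            continue
        r = grp["ratio"].to_numpy()
        pct = 100.0 * (r.mean() - neg) / span
        se = 100.0 * (r.std(ddof=1) / np.sqrt(len(r)) / span) if len(r) > 1 else float("nan")
        out.append(RelativeActivity(cid, float(pct), float(se), len(r)))
    return out


@dataclass(frozen=True)
class PerMotifComparison:
    delta: float                 # activity drop, percent (2 decimals)
    per_motif: float             # delta / total motifs added (2 decimals)
    motifs_added: dict[str, int]
    attributed_to: str           # dominant added motif type


def per_motif_effect(
    act_a: float,
    act_b: float,
    struct_a: AlleleStructure | str,
    struct_b: AlleleStructure | str,
) -> PerMotifComparison:
    """Pairwise per-motif effect between a smaller (a) and larger (b) construct.

    ``struct_b`` must extend ``struct_a`` (no motif type lost); the drop in
    activity is divided by the total number of motifs added and attributed to
    the dominant added type.  Values are reported to 2 decimals.
    """
    if isinstance(struct_a, str):
        struct_a = parse_nomenclature(struct_a)
    if isinstance(struct_b, str):
        struct_b = parse_nomenclature(struct_b)
    ca, cb = struct_a.motif_counts(), struct_b.motif_counts()
    added = {m: cb.get(m, 0) - ca.get(m, 0) for m in set(ca) | set(cb)}
    if any(v < 0 for v in added.values()):
        negs = [m for m, v in added.items() if v < 0]
        raise UsageError(
            f"structures are not comparable: larger construct lacks {negs} "
            "motifs present in the smaller one"
        )
    added = {m: v for m, v in added.items() if v > 0}
    total = sum(added.values())
    delta = round(act_a - act_b, 2)
    if total == 0:
        return PerMotifComparison(delta, 0.0, {}, "")
    per = round(delta / total, 2)
    dominant = max(added, key=lambda m: (added[m], m))
    return PerMotifComparison(delta, per, added, dominant)


@dataclass
class MotifActivityResults:
    """OLS estimates of percent activity change per added motif of each type."""

    params: pd.Series          # intercept + one beta per motif type
    bse: pd.Series
    resid: np.ndarray
    rsquared: float
    loo_params: pd.DataFrame   # leave-one-construct-out refits
    nobs: int
    fit_method: str = "ols"

    @property
    def intercept(self) -> float:
        return float(self.params["intercept"])

    def beta(self, motif_id: str) -> float:
        return float(self.params[motif_id])

    def loo_range(self) -> pd.Series:
        """Spread (max - min) of each coefficient over leave-one-out refits."""
        return self.loo_params.max() - self.loo_params.min()

    def summary(self) -> str:
        tbl = pd.DataFrame({"coef": self.params, "se": self.bse})
        return (
            "Per-motif activity model (percent ~ intercept + sum beta_type * count_type)\n"
            f"  n constructs: {self.nobs}   R^2: {self.rsquared:.4f}\n\n"
            + tbl.to_string(float_format=lambda x: f"{x: .4f}")
        )


class MotifActivityModel:
    """Linear model of relative activity on per-type motif counts.

    Parameters
    ----------
    activities : sequence of (RelativeActivity, AlleleStructure) or DataFrame
        One row per construct with its percent activity and decomposed
        structure.
    """

    def __init__(
        self,
        activities: Sequence[RelativeActivity],
        structures: Sequence[AlleleStructure],
        alphabet=DEFAULT_ALPHABET,
    ):
        if len(activities) != len(structures):
            raise UsageError("activities and structures must align")
        if len(activities) < 4:
            raise UsageError("at least 4 constructs with distinct motif counts are required")
        self.activities = list(activities)
        self.structures = list(structures)
        self.motif_types = list(alphabet.ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, alphabet=DEFAULT_ALPHABET):
        """Columns: construct_id (nomenclature string), percent[, se, n]."""
        acts, structs = [], []
        for _, row in df.iterrows():
            acts.append(
                RelativeActivity(
                    row["construct_id"],
                    float(row["percent"]),
                    float(row.get("se", float("nan"))),
                    int(row.get("n", 1)),
                )
            )
            structs.append(parse_nomenclature(row["construct_id"], alphabet))
        return cls(acts, structs, alphabet)

    def _design(self, idx=None) -> tuple[np.ndarray, np.ndarray]:
        rows = range(len(self.activities)) if idx is None else idx
        X = np.array(
            [
                [1.0] + [self.structures[i].motif_counts().get(m, 0) for m in self.motif_types]
                for i in rows
            ]
        )
        y = np.array([self.activities[i].percent for i in rows])
        return X, y

    def fit(self) -> MotifActivityResults:
        import statsmodels.api as sm

        X, y = self._design()
        names = ["intercept"] + self.motif_types
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the collinear columns for the error message
            raise FitError(
                f"rank-deficient design (rank {rank} < {X.shape[1]}): motif "
                f"count columns {self.motif_types} are collinear across constructs"
            )
        res = sm.OLS(y, X).fit()
        params = pd.Series(res.params, index=names)
        bse = pd.Series(res.bse, index=names)
        loo = []
        for drop in range(len(self.activities)):
            idx = [i for i in range(len(self.activities)) if i != drop]
            Xi, yi = self._design(idx)
            if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
                continue
            loo.append(np.linalg.lstsq(Xi, yi, rcond=None)[0])
        loo_df = pd.DataFrame(loo, columns=names)
        return MotifActivityResults(
            params=params,
            bse=bse,
            resid=np.asarray(res.resid),
            rsquared=float(res.rsquared) if y.var() > 0 else 1.0,
            loo_params=loo_df,
            nobs=len(y),
        )


fit_motif_model = MotifActivityModel  # conventional alias for the class entry point


@dataclass
class TukeyPair:
    group1: str
    group2: str
    meandiff: float
    p_adj: float
    significant: bool


@dataclass
class AnovaTukeyReport:
    F: float
    p_value: float
    alpha: float
    pairs: list[TukeyPair]

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [(p.group1, p.group2) for p in self.pairs if p.significant]

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA: F = {self.F:.4f}, p = {self.p_value:.4g} (alpha = {self.alpha})",
            "Tukey HSD:",
        ]
        for p in self.pairs:
            flag = "*" if p.significant else " "
            lines.append(
                f"  {p.group1} vs {p.group2}: diff = {p.meandiff: .3f}, "
                f"p_adj = {p.p_adj:.4g} {flag}"
            )
        return "\n".join(lines)


def one_way_anova_tukey(groups: dict[str, Sequence[float]], alpha: float = 0.05) -> AnovaTukeyReport:
    """One-way ANOVA across construct groups with Tukey HSD post hoc tests."""
    if len(groups) < 2:
        raise UsageError("at least two groups are required")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise UsageError(f"group {name!r} has fewer than 2 replicates")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    F, p = stats.f_oneway(*arrays)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    labels = np.concatenate([[name] * len(v) for name, v in groups.items()])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = [
        TukeyPair(str(g1), str(g2), float(md), float(padj), bool(rej))
        for g1, g2, md, padj, rej in zip(
            tk.groupsunique[tk._multicomp.pairindices[0]],
            tk.groupsunique[tk._multicomp.pairindices[1]],
            tk.meandiffs,
            tk.pvalues,
            tk.reject,
        )
    ]
    return AnovaTukeyReport(float(F), float(p), alpha, pairs)
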