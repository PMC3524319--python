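"""Time-course expression screening for priming candidates.

The pipeline takes a probes x samples expression matrix from a
six-condition design — Control, LD (low-dose alone), HD at 3 h and 24 h,
and LD+HD at 3 h and 24 h, with replicate pools — and

1. filters undetected probes (detection-call filter) and probes with no
   >= 2-fold change in any of the five treatment-vs-Control comparisons,
   testing differential expression with Welch's t-test on log2 values
   and Benjamini-Hochberg FDR correction at p < 0.05;
2. classifies each surviving gene's LD response (induced / reduced /
   silent) and its response dynamics under the HD and LD+HD arms
   (early = 3 h only, late = 24 h only, persistent = both, silent);
3. identifies readout candidates (negligible LD response but higher
   LD+HD than HD response) in a relaxed and a strict tier;
4. assigns mechanism roles (PS-regulator, AI-regulator, SD-suppressor,
   HD-partner) for downstream network matching; and
5. quantifies how the LD pretreatment reshuffles genes among the
   dynamics groups between the HD and LD+HD arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONDITIONS = ("Control", "LD", "HD3", "HD24", "LDHD3", "LDHD24")

#: the five treatment-vs-Control comparisons of the non-trivial-dynamics filter
SCREEN_COMPARISONS = (
    ("LD", "Control"),
    ("HD3", "Control"),
    ("HD24", "Control"),
    ("LDHD3", "Control"),
    ("LDHD24", "Control"),
)


@dataclass
class ComparisonSpec:
    """One differential-expression contrast."""

    numerator: str
    denominator: str
    fc_threshold: float = 2.0
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be > 0")


class ExpressionMatrix:
    """Probes x samples expression values with sample condition metadata.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, columns are sample names; linear
        scale, strictly positive.
    conditions, replicates
        Per-sample condition label and replicate-pool number.
    calls
        Optional detection calls, same shape as ``values``, entries in
        {"P", "A", "M"} (Present / Absent / Marginal).
    symbols
        Optional probe -> gene symbol mapping.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        conditions: dict[str, str],
        replicates: dict[str, int],
        calls: pd.DataFrame | None = None,
        symbols: pd.Series | None = None,
    ):
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate probe id {dup!r}")
        if not np.isfinite(values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if (values.to_numpy() <= 0).any():
            raise ValueError("expression values must be positive (linear scale)")
        unknown = set(conditions.values()) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        missing = [c for c in values.columns if c not in conditions]
        if missing:
            raise ValueError(f"samples without condition metadata: {missing}")
        if calls is not None and (
            not calls.index.equals(values.index)
            or list(calls.columns) != list(values.columns)
        ):
            raise ValueError("detection calls must align with the value matrix")
        self.values = values
        self.conditions = dict(conditions)
        self.replicates = dict(replicates)
        self.calls = calls
        self.symbols = symbols

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    def samples_of(self, condition: str) -> list[str]:
        cols = [c for c in self.values.columns if self.conditions[c] == condition]
        if not cols:
            raise KeyError(f"no samples with condition {condition!r}")
        return cols

    def condition_values(self, condition: str) -> pd.DataFrame:
        return self.values[self.samples_of(condition)]

    def subset(self, probes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[probes],
            self.conditions,
            self.replicates,
            self.calls.loc[probes] if self.calls is not None else None,
            self.symbols.loc[probes] if self.symbols is not None else None,
        )


def present_call_filter(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Drop probes with no Present call in any sample of any pool.

    Identity (with a warning) when the matrix carries no detection calls.
    """
    if mat.calls is None:
        logger.warning("no detection calls available; present-call filter skipped")
        return mat
    keep = (mat.calls == "P").any(axis=1)
    return mat.subset(mat.probes[keep])


def fold_change(
    mat: ExpressionMatrix, spec: ComparisonSpec
) -> pd.DataFrame:
    """Per-probe fold change between two conditions.

    FC = mean(numerator replicates) / mean(denominator replicates) on the
    linear scale, with the signed direction (+1 up, -1 down).
    """
    num = mat.condition_values(spec.numerator).mean(axis=1)
    den = mat.condition_values(spec.denominator).mean(axis=1)
    if (den == 0).any():
        raise ZeroDivisionError("zero denominator mean")
    fc = num / den
    return pd.DataFrame({"fc": fc, "direction": np.sign(fc - 1.0).astype(int)})


def welch_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch's t-test p-value on log2-transformed values.

    Degenerate cases: both groups constant with equal means -> p = 1;
    both constant with unequal means -> p = 0 (flagged in the log).
    """
    a = np.log2(np.asarray(a, dtype=float))
    b = np.log2(np.asarray(b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 1.0
        logger.warning("zero variance in both groups with unequal means; p -> 0")
        return 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def welch_test_matrix(
    mat: ExpressionMatrix, num: str, den: str
) -> pd.Series:
    """Vectorized Welch test of two conditions across all probes."""
    a = np.log2(mat.condition_values(num).to_numpy())
    b = np.log2(mat.condition_values(den).to_numpy())
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate rows: zero variance in both groups
    both_const = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    if both_const.any():
        eq = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[both_const & eq] = 1.0
        p[both_const & ~eq] = 0.0
    return pd.Series(p, index=mat.probes, name=f"{num}_vs_{den}")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreenResult:
    """Differential-expression table of all five screen comparisons.

    ``table`` has a two-level column index (comparison, {fc, p, p_adj,
    significant}); significance = FC >= threshold AND adjusted p < alpha,
    in either direction (fold changes below 1/threshold count as
    down-regulation).
    """

    table: pd.DataFrame
    specs: dict[str, ComparisonSpec] = field(default_factory=dict)

    def significant(self, comparison: str) -> pd.Series:
        return self.table[(comparison, "significant")]

    def up(self, comparison: str) -> pd.Series:
        return self.significant(comparison) & (self.table[(comparison, "fc")] > 1)

    def down(self, comparison: str) -> pd.Series:
        return self.significant(comparison) & (self.table[(comparison, "fc")] < 1)


def fold_change_filter(
    mat: ExpressionMatrix,
    comparisons=SCREEN_COMPARISONS,
    fc_threshold: float = 2.0,
) -> ExpressionMatrix:
    """Drop probes without a >= threshold fold change in any comparison.

    This runs before the statistical testing, so the multiple-testing
    correction is applied over the fold-change survivors only.
    """
    keep = pd.Series(False, index=mat.probes)
    for num, den in comparisons:
        fc = fold_change(mat, ComparisonSpec(num, den, fc_threshold))["fc"]
        keep |= (fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)
    return mat.subset(mat.probes[keep])


def screen_comparisons(
    mat: ExpressionMatrix,
    comparisons=SCREEN_COMPARISONS,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> ScreenResult:
    """Run FC + Welch + BH for a list of (numerator, denominator) pairs.

    The BH correction is applied per comparison across all probes in the
    matrix (the matrix should already be detection-filtered).
    """
    blocks = {}
    specs = {}
    for num, den in comparisons:
        name = f"{num}_vs_{den}"
        spec = ComparisonSpec(num, den, fc_threshold, p_threshold)
        fc = fold_change(mat, spec)["fc"]
        p = welch_test_matrix(mat, num, den)
        p_adj = pd.Series(bh_fdr(p), index=mat.probes)
        sig = (
            ((fc >= fc_threshold) | (fc <= 1.0 / fc_threshold))
            & (p_adj < p_threshold)
        )
        blocks[name] = pd.DataFrame(
            {"fc": fc, "p": p, "p_adj": p_adj, "significant": sig}
        )
        specs[name] = spec
    table = pd.concat(blocks, axis=1)
    return ScreenResult(table=table, specs=specs)


def select_nontrivial(mat: ExpressionMatrix, screen: ScreenResult) -> pd.Index:
    """Probes with a significant >= 2-fold change in >= 1 screen comparison."""
    sig = pd.concat(
        [screen.significant(c) for c in screen.specs], axis=1
    ).any(axis=1)
    return mat.probes[sig]


def classify_ld_response(screen: ScreenResult) -> pd.Series:
    """LD-induced / LD-reduced / LD-silent per probe (LD vs Control)."""
    cmp = "LD_vs_Control"
    out = pd.Series("LD-silent", index=screen.table.index, name="ld_class")
    out[screen.up(cmp)] = "LD-induced"
    out[screen.down(cmp)] = "LD-reduced"
    return out


def classify_dynamics(screen: ScreenResult, arm: str) -> pd.Series:
    """Early / late / persistent / silent response dynamics of one arm.

    ``arm`` is ``"HD"`` or ``"LDHD"``; significance (either direction) at
    3 h only -> early, at 24 h only -> late, both -> persistent.
    """
    if arm not in ("HD", "LDHD"):
        raise ValueError("arm must be 'HD' or 'LDHD'")
    s3 = screen.significant(f"{arm}3_vs_Control")
    s24 = screen.significant(f"{arm}24_vs_Control")
    out = pd.Series("silent", index=screen.table.index, name=f"dynamics_{arm}")
    out[s3 & ~s24] = "early"
    out[~s3 & s24] = "late"
    out[s3 & s24] = "persistent"
    return out


def identify_readouts(
    mat: ExpressionMatrix,
    screen: ScreenResult,
    ld_class: pd.Series,
    relaxed_fc: float = 1.5,
    strict_fc: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Readout candidates: LD-silent genes with LD+HD above HD.

    The relaxed tier mirrors the model-level priming excess: LD-silent
    and LD+HD / HD fold change >= ``relaxed_fc`` at a matching time
    point.  The strict tier additionally requires FC >= ``strict_fc``
    with BH-adjusted p < ``p_threshold`` on the LD+HD vs HD contrast.
    """
    ldhd_vs_hd = screen_comparisons(
        mat,
        comparisons=(("LDHD3", "HD3"), ("LDHD24", "HD24")),
        fc_threshold=strict_fc,
        p_threshold=p_threshold,
    )
    relaxed = pd.Series(False, index=mat.probes)
    strict = pd.Series(False, index=mat.probes)
    for cmp_name in ("LDHD3_vs_HD3", "LDHD24_vs_HD24"):
        fc = ldhd_vs_hd.table[(cmp_name, "fc")]
        relaxed |= fc >= relaxed_fc
        strict |= ldhd_vs_hd.up(cmp_name)
    silent = ld_class == "LD-silent"
    return pd.DataFrame(
        {
            "readout_relaxed": relaxed & silent,
            "readout_strict": strict & silent,
        }
    )


def assign_mechanism_roles(
    mat: ExpressionMatrix,
    screen: ScreenResult,
    ld_class: pd.Series,
    dynamics_hd: pd.Series,
    ldhd_similar_delta: float = 1.5,
) -> pd.DataFrame:
    """Mechanism roles each gene can serve in a priming motif.

    - PS-regulator: LD-induced with a clearly higher LD+HD than HD
      response (ratio >= ``ldhd_similar_delta`` at some time point);
    - AI-regulator: LD-induced with LD+HD similar to HD (no time point
      reaches the ratio);
    - SD-suppressor: LD-reduced;
    - HD-partner: LD-silent but HD-responsive (any dynamics class).
    """
    r3 = (
        mat.condition_values("LDHD3").mean(axis=1)
        / mat.condition_values("HD3").mean(axis=1)
    )
    r24 = (
        mat.condition_values("LDHD24").mean(axis=1)
        / mat.condition_values("HD24").mean(axis=1)
    )
    boosted = (r3 >= ldhd_similar_delta) | (r24 >= ldhd_similar_delta)
    induced = ld_class == "LD-induced"
    roles = pd.DataFrame(
        {
            "PS-regulator": induced & boosted,
            "AI-regulator": induced & ~boosted,
            "SD-suppressor": ld_class == "LD-reduced",
            "HD-partner": (ld_class == "LD-silent") & (dynamics_hd != "silent"),
        }
    )
    return roles


@dataclass
class ReshuffleResult:
    """Dynamics-group membership changes between the HD and LD+HD arms."""

    transition: pd.DataFrame  # rows: HD-arm class, cols: LD+HD-arm class
    switched_off: pd.Index    # responsive under HD, silent under LD+HD
    switched_on: pd.Index     # silent under HD, responsive under LD+HD
    reshuffled: pd.Index      # responsive in both arms, different class

    @property
    def n_early_to_late_or_persistent(self) -> int:
        return int(
            self.transition.loc["early", ["late", "persistent"]].sum()
        )

    @property
    def n_late_to_early_or_persistent(self) -> int:
        return int(
            self.transition.loc["late", ["early", "persistent"]].sum()
        )


DYNAMICS_CLASSES = ("early", "late", "persistent", "silent")


def reshuffle_analysis(
    class_hd: pd.Series, class_ldhd: pd.Series
) -> ReshuffleResult:
    """Transition matrix of dynamics classes between the two arms."""
    if not class_hd.index.equals(class_ldhd.index):
        raise ValueError("classifications must cover the same probes")
    trans = pd.DataFrame(
        0, index=list(DYNAMICS_CLASSES), columns=list(DYNAMICS_CLASSES)
    )
    for a in DYNAMICS_CLASSES:
        in_a = class_hd == a
        for b in DYNAMICS_CLASSES:
            trans.loc[a, b] = int((in_a & (class_ldhd == b)).sum())
    responsive_hd = class_hd != "silent"
    responsive_ldhd = class_ldhd != "silent"
    return ReshuffleResult(
        transition=trans,
        switched_off=class_hd.index[responsive_hd & ~responsive_ldhd],
        switched_on=class_hd.index[~responsive_hd & responsive_ldhd],
        reshuffled=class_hd.index[
            responsive_hd & responsive_ldhd & (class_hd != class_ldhd)
        ],
    )


@dataclass
class ScreenSummary:
    """End-to-end screening output for one expression matrix."""

    n_input_probes: int
    n_detected: int
    nontrivial: pd.Index
    classification: pd.DataFrame
    roles: pd.DataFrame
    reshuffle: ReshuffleResult
    screen: ScreenResult

    def counts(self) -> dict:
        cl = self.classification
        return {
            "n_input_probes": self.n_input_probes,
            "n_detected": self.n_detected,
            "n_nontrivial": len(self.nontrivial),
            "n_ld_induced": int((cl["ld_class"] == "LD-induced").sum()),
            "n_ld_reduced": int((cl["ld_class"] == "LD-reduced").sum()),
            "n_hd_early": int((cl["dynamics_HD"] == "early").sum()),
            "n_hd_late": int((cl["dynamics_HD"] == "late").sum()),
            "n_hd_persistent": int((cl["dynamics_HD"] == "persistent").sum()),
            "n_ldhd_early": int((cl["dynamics_LDHD"] == "early").sum()),
            "n_readout_relaxed": int(cl["readout_relaxed"].sum()),
            "n_readout_strict": int(cl["readout_strict"].sum()),
            "n_early_to_late_or_persistent":
                self.reshuffle.n_early_to_late_or_persistent,
            "n_late_to_early_or_persistent":
                self.reshuffle.n_late_to_early_or_persistent,
        }


def run_screen(
    mat: ExpressionMatrix,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    relaxed_fc: float = 1.5,
) -> ScreenSummary:
    """The full screening pipeline on one matrix.

    Order: detection-call filter; fold-change filter over the five
    treatment-vs-Control comparisons; Welch + BH testing over the
    fold-change survivors; restriction to non-trivially-responding
    genes; LD and dynamics classification; readout identification; role
    assignment; reshuffle analysis between the HD and LD+HD arms.
    """
    n_input = len(mat.probes)
    detected = present_call_filter(mat)
    candidates = fold_change_filter(detected, fc_threshold=fc_threshold)
    screen = screen_comparisons(
        candidates, fc_threshold=fc_threshold, p_threshold=p_threshold
    )
    nontrivial = select_nontrivial(candidates, screen)
    sub = candidates.subset(nontrivial)
    sub_screen = ScreenResult(
        table=screen.table.loc[nontrivial], specs=screen.specs
    )
    ld_class = classify_ld_response(sub_screen)
    dyn_hd = classify_dynamics(sub_screen, "HD")
    dyn_ldhd = classify_dynamics(sub_screen, "LDHD")
    readouts = identify_readouts(
        sub, sub_screen, ld_class,
        relaxed_fc=relaxed_fc, p_threshold=p_threshold,
    )
    roles = assign_mechanism_roles(sub, sub_screen, ld_class, dyn_hd)
    classification = pd.concat(
        [
            ld_class,
            dyn_hd.rename("dynamics_HD"),
            dyn_ldhd.rename("dynamics_LDHD"),
            readouts,
        ],
        axis=1,
    )
    if mat.symbols is not None:
        classification.insert(0, "symbol", mat.symbols.loc[nontrivial])
    return ScreenSummary(
        n_input_probes=n_input,
        n_detected=len(detected.probes),
        nontrivial=nontrivial,
        classification=classification,
        roles=roles,
        reshuffle=reshuffle_analysis(dyn_hd, dyn_ldhd),
        screen=sub_screen,
    )
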