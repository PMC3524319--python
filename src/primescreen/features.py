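"""Priming feature extraction, criteria, and mechanism classification.

The dose-response definition of priming on a readout x3:

1. LD alone does not activate the readout (max below ``tau_ld``, in
   reduced units where 1 is the maximal induction);
2. HD alone does activate it (max at least ``tau_hd``);
3. the sequential LD+HD maximum exceeds the HD-alone maximum by at least
   a fraction ``rho`` (default 50%).

Primed systems are classified by where the regulators sit after the LD
pretreatment (Delta-ss, change at the end of the LD period relative to
the untreated baseline) and how their maxima during the HD window shift
when the LD pretreatment is added (Delta-max difference), with a single
resolution cutoff ``delta``:

- Suppressor Deactivation (SD): a regulator drops below ``-delta`` under
  LD — the pretreatment relieves an inhibitor of the readout.
- Pathway Synergy (PS): a regulator rises above ``+delta`` under LD and
  its HD-window maximum is raised by more than ``delta`` when primed —
  a slow low-threshold activator is brought forward to synergize with
  the fast pathway.
- Activator Induction (AI): a regulator rises above ``+delta`` under LD
  but its HD-window maximum is unchanged (within ``delta``) — the
  pre-induced activator outruns an HD-induced inhibitor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import TimeCourseSet

__all__ = [
    "PrimingFeatures",
    "PrimingThresholds",
    "MechanismLabel",
    "extract_features",
    "evaluate_priming",
    "classify_mechanism",
]


@dataclass(frozen=True)
class PrimingThresholds:
    """Cutoffs of the priming definition and the mechanism classifier.

    All in reduced units (1 = maximal induction) unless the trajectories
    carry other units, in which case the thresholds follow those units.
    """

    tau_ld: float = 0.1   # LD non-response bound on the readout
    tau_hd: float = 0.1   # HD activation bound on the readout
    rho: float = 0.5      # required fractional excess of LD+HD over HD
    delta: float = 0.1    # Delta-ss / Delta-max resolution cutoff

    def __post_init__(self) -> None:
        if min(self.tau_ld, self.tau_hd, self.delta) < 0 or self.rho <= 0:
            raise ValueError("thresholds must be >= 0 and rho > 0")


@dataclass
class PrimingFeatures:
    """Per-regulator summary statistics of the four experimental arms.

    ``dss_ld[v]`` is the level of ``v`` at the end of the LD period minus
    the untreated baseline.  ``dmax_hd[v]`` / ``dmax_ldhd[v]`` are the
    maxima of ``v`` over the HD treatment window of the HD / LD+HD arms,
    minus the same baseline.  Readout maxima are absolute levels.
    """

    dss_ld: dict[str, float]
    dmax_hd: dict[str, float]
    dmax_ldhd: dict[str, float]
    readout_max_ld: float
    readout_max_hd: float
    readout_max_ldhd: float
    readout: str = "x3"
    baseline: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = (
            list(self.dss_ld.values())
            + list(self.dmax_hd.values())
            + list(self.dmax_ldhd.values())
            + [self.readout_max_ld, self.readout_max_hd, self.readout_max_ldhd]
        )
        if not np.all(np.isfinite(vals)):
            raise ValueError("priming features must be finite")

    def dmax_diff(self, var: str) -> float:
        """Delta-max under LD+HD minus Delta-max under HD alone."""
        return self.dmax_ldhd[var] - self.dmax_hd[var]

    def to_dict(self) -> dict:
        return {
            "readout": self.readout,
            "dss_ld": dict(self.dss_ld),
            "dmax_hd": dict(self.dmax_hd),
            "dmax_ldhd": dict(self.dmax_ldhd),
            "readout_max_ld": self.readout_max_ld,
            "readout_max_hd": self.readout_max_hd,
            "readout_max_ldhd": self.readout_max_ldhd,
        }


@dataclass
class MechanismLabel:
    """Mechanism call with the feature comparisons that fired."""

    label: str  # PS | AI | SD | none
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in ("PS", "AI", "SD", "none"):
            raise ValueError(f"unknown mechanism label {self.label!r}")
        if self.label != "none" and not self.evidence:
            raise ValueError("a mechanism label needs evidence")


def extract_features(
    tcs: TimeCourseSet,
    readout_name: str,
    ld_period: tuple[float, float],
    hd_period: tuple[float, float],
    regulators: tuple[str, ...] | None = None,
) -> PrimingFeatures:
    """Compute Delta-ss / Delta-max features from the four arms.

    ``ld_period`` and ``hd_period`` are absolute time windows on the shared
    grid; the HD windows of the HD and LD+HD arms are assumed aligned (as
    produced by :func:`primescreen.protocols.standard_protocols`).
    The baseline is the untreated trajectory's level at protocol start
    (systems are expected to be pre-relaxed to steady state).
    """
    for label in ("untreated", "LD", "HD", "LD_HD"):
        if label not in tcs:
            raise KeyError(f"TimeCourseSet lacks the {label!r} arm")
    unt, ld, hd, ldhd = (tcs[k] for k in ("untreated", "LD", "HD", "LD_HD"))
    if regulators is None:
        regulators = tuple(n for n in unt.names if n != readout_name)
    baseline = {v: unt.value_at(v, unt.times[0]) for v in unt.names}

    dss_ld, dmax_hd, dmax_ldhd = {}, {}, {}
    for v in regulators:
        dss_ld[v] = ld.value_at(v, ld_period[1]) - baseline[v]
        dmax_hd[v] = hd.max_in(v, *hd_period) - baseline[v]
        dmax_ldhd[v] = ldhd.max_in(v, *hd_period) - baseline[v]

    return PrimingFeatures(
        dss_ld=dss_ld,
        dmax_hd=dmax_hd,
        dmax_ldhd=dmax_ldhd,
        readout_max_ld=ld.max_in(readout_name, ld.times[0], ld.times[-1]),
        readout_max_hd=hd.max_in(readout_name, *hd_period),
        readout_max_ldhd=ldhd.max_in(readout_name, ldhd.times[0], ldhd.times[-1]),
        readout=readout_name,
        baseline=baseline,
    )


def evaluate_priming(
    features: PrimingFeatures, th: PrimingThresholds | None = None
) -> dict:
    """Apply the three dose-response clauses of the priming definition.

    Returns ``{"primed": bool, "reason": str}``; ``reason`` names the
    first failed clause, or is ``"all clauses satisfied"``.
    """
    th = th or PrimingThresholds()
    if features.readout_max_ld >= th.tau_ld:
        return {
            "primed": False,
            "reason": (
                f"LD clause: readout max {features.readout_max_ld:.4g} "
                f">= tau_ld {th.tau_ld}"
            ),
        }
    if features.readout_max_hd < th.tau_hd:
        return {
            "primed": False,
            "reason": (
                f"HD clause: readout max {features.readout_max_hd:.4g} "
                f"< tau_hd {th.tau_hd}"
            ),
        }
    need = (1.0 + th.rho) * features.readout_max_hd
    # tiny slack keeps the inclusive boundary robust to representation error
    if features.readout_max_ldhd < need - 1e-12:
        return {
            "primed": False,
            "reason": (
                f"ratio clause: LD+HD max {features.readout_max_ldhd:.4g} "
                f"< (1+rho) x HD max = {need:.4g}"
            ),
        }
    return {"primed": True, "reason": "all clauses satisfied"}


def classify_mechanism(
    features: PrimingFeatures,
    th: PrimingThresholds | None = None,
    graph=None,
) -> MechanismLabel:
    """Assign a primed system to SD / PS / AI by its regulator features.

    Requires :func:`evaluate_priming` to have returned primed; the
    classifier of a non-primed system returns ``none``.  When a signed
    ``graph`` (:class:`primescreen.motifs.SignedGraph`) is supplied, the
    sign of the regulator-to-readout path must agree with the mechanism
    template (SD regulator inhibits, PS/AI regulator activates; for AI
    some HD-responsive partner inhibits the readout).

    When distinct regulators fire different rules simultaneously, all
    firing rules are kept in the evidence and the label follows the
    precedence SD > PS > AI.
    """
    th = th or PrimingThresholds()
    if not evaluate_priming(features, th)["primed"]:
        return MechanismLabel("none")

    if graph is not None and features.readout not in graph:
        raise KeyError(
            f"readout {features.readout!r} is absent from the supplied graph"
        )

    def path_signs(reg: str) -> set[int]:
        if graph is None:
            return {1, -1}  # no topology info: any sign admissible
        return graph.path_signs(reg, features.readout)

    evidence: list[str] = []
    fired: list[str] = []
    regulators = sorted(features.dss_ld)

    for v in regulators:
        if features.dss_ld[v] < -th.delta and -1 in path_signs(v):
            fired.append("SD")
            evidence.append(
                f"SD: dss_ld[{v}] = {features.dss_ld[v]:.4g} < -delta"
            )
    for v in regulators:
        if features.dss_ld[v] > th.delta:
            diff = features.dmax_diff(v)
            if diff > th.delta and 1 in path_signs(v):
                fired.append("PS")
                evidence.append(
                    f"PS: dss_ld[{v}] = {features.dss_ld[v]:.4g} > delta and "
                    f"dmax diff = {diff:.4g} > delta"
                )
            elif abs(diff) <= th.delta and 1 in path_signs(v):
                # AI needs an antagonist: with a graph, some other
                # regulator must inhibit the readout.
                others_inhibit = graph is None or any(
                    -1 in path_signs(u) for u in regulators if u != v
                )
                if others_inhibit:
                    fired.append("AI")
                    evidence.append(
                        f"AI: dss_ld[{v}] = {features.dss_ld[v]:.4g} > delta "
                        f"and |dmax diff| = {abs(diff):.4g} <= delta"
                    )
    for label in ("SD", "PS", "AI"):
        if label in fired:
            return MechanismLabel(label, evidence)
    return MechanismLabel("none")
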