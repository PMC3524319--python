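"""Synthetic data emulating the six-condition priming microarray design.

The generator plants known gene classes into a probes x samples matrix
with the structure of the IFN-gamma priming experiment the screening
pipeline targets: ~12,000 probes, six condition groups (Control, LD,
HD 3 h, HD 24 h, LD+HD 3 h, LD+HD 24 h), three replicate pools,
multiplicative log-normal noise, and Present/Absent detection calls.
Planted classes (LD-induced split into PS- and AI-style responders,
LD-reduced, HD-early/late/persistent, dynamics reshufflers, readouts)
mirror the gene-group counts of the study design; effect sizes and the
noise level are synthetic choices.

Also provides planted signed regulatory networks whose PS/AI/SD motifs
are recoverable by the motif matcher, and hand-constructed three-node
exemplar parameter sets, one per priming mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import CONDITIONS, ExpressionMatrix
from .motifs import SignedGraph
from .trinode import CANONICAL_TOPOLOGIES, TriNodeParams, TriNodeTopology


@dataclass
class SyntheticSpec:
    """Design of one synthetic expression data set.

    Class sizes default to the printed gene-group counts of the emulated
    study (27 LD-induced, 20 LD-reduced, 78 early, 5 readouts, 5 + 17
    reshufflers); late/persistent sizes, fold changes (4x), the log2
    noise sigma (0.2) and the absent fraction are this package's own
    realistic defaults.
    """

    n_probes: int = 12000
    n_replicates: int = 3
    n_ld_induced: int = 27
    n_ld_reduced: int = 20
    n_hd_early: int = 78
    n_hd_late: int = 40
    n_hd_persistent: int = 35
    n_readouts: int = 5
    n_reshuffle_early: int = 5   # early under HD -> late/persistent under LD+HD
    n_reshuffle_late: int = 17   # late under HD -> early/persistent under LD+HD
    effect_fc: float = 4.0       # planted fold change of responsive classes
    readout_hd_fc: float = 1.3   # readouts: sub-threshold HD response
    readout_boost: float = 2.5   # readouts: LD+HD over HD ratio
    sigma_log2: float = 0.2      # replicate noise, log2 scale
    absent_fraction: float = 0.05
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log2 <= 0:
            raise ValueError("sigma_log2 must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates for testing")
        if self.total_planted + int(self.absent_fraction * self.n_probes) > self.n_probes:
            raise ValueError("planted classes exceed the number of probes")
        if self.n_reshuffle_early > self.n_hd_early:
            raise ValueError("more early reshufflers than early genes")
        if self.n_reshuffle_late > self.n_hd_late:
            raise ValueError("more late reshufflers than late genes")

    @property
    def total_planted(self) -> int:
        return (
            self.n_ld_induced + self.n_ld_reduced + self.n_hd_early
            + self.n_hd_late + self.n_hd_persistent + self.n_readouts
        )


@dataclass
class GroundTruth:
    """Planted per-probe labels, consistent with the matrix by construction."""

    ld_class: pd.Series            # LD-induced / LD-reduced / LD-silent
    dynamics_hd: pd.Series         # early / late / persistent / silent
    dynamics_ldhd: pd.Series
    roles: pd.DataFrame            # boolean role columns per probe
    readouts: pd.Index
    absent: pd.Index
    reshufflers: pd.Index
    symbols: pd.Series
    spec: SyntheticSpec = None

    @property
    def nontrivial(self) -> pd.Index:
        mask = (
            (self.ld_class != "LD-silent")
            | (self.dynamics_hd != "silent")
            | (self.dynamics_ldhd != "silent")
        )
        return self.ld_class.index[mask]


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one synthetic matrix plus its ground truth.

    Baselines are log-normal across probes; class effects multiply the
    condition means; replicates get i.i.d. multiplicative log-normal
    noise.  Deterministic for a fixed spec (seeded).
    """
    rng = np.random.default_rng(spec.seed)
    probes = pd.Index(
        [f"probe_{i:05d}" for i in range(spec.n_probes)], name="probe"
    )
    symbols = pd.Series([f"GENE{i:05d}" for i in range(spec.n_probes)], index=probes)

    # block assignment of planted classes
    cursor = 0

    def take(n):
        nonlocal cursor
        block = probes[cursor:cursor + n]
        cursor += n
        return block

    ld_induced = take(spec.n_ld_induced)
    # LD-induced genes split into PS-style (LD+HD above HD) and AI-style
    # (LD+HD similar to HD) responders
    n_ps = spec.n_ld_induced - spec.n_ld_induced // 2
    ld_induced_ps, ld_induced_ai = ld_induced[:n_ps], ld_induced[n_ps:]
    ld_reduced = take(spec.n_ld_reduced)
    hd_early = take(spec.n_hd_early)
    hd_late = take(spec.n_hd_late)
    hd_persistent = take(spec.n_hd_persistent)
    readouts = take(spec.n_readouts)
    n_absent = int(spec.absent_fraction * spec.n_probes)
    absent = take(n_absent)

    resh_early = hd_early[: spec.n_reshuffle_early]
    resh_late = hd_late[: spec.n_reshuffle_late]

    # per-condition mean multipliers (relative to baseline)
    F, rb, rhd = spec.effect_fc, spec.readout_boost, spec.readout_hd_fc
    mult = pd.DataFrame(1.0, index=probes, columns=list(CONDITIONS))
    # PS-style LD-induced: respond to LD, amplified under LD+HD
    mult.loc[ld_induced_ps, ["LD", "LDHD3", "LDHD24"]] = F
    # AI-style LD-induced: respond to LD and HD alike (LD+HD ~ HD)
    mult.loc[ld_induced_ai, ["LD", "HD3", "HD24", "LDHD3", "LDHD24"]] = F
    mult.loc[ld_reduced, ["LD", "LDHD3", "LDHD24"]] = 1.0 / F
    mult.loc[hd_early, ["HD3", "LDHD3"]] = F
    mult.loc[hd_late, ["HD24", "LDHD24"]] = F
    mult.loc[hd_persistent, ["HD3", "HD24", "LDHD3", "LDHD24"]] = F

    # arm-wise dynamics implied by the planted multipliers (changes in
    # either direction count as a response at that time point)
    dyn_hd = pd.Series("silent", index=probes)
    dyn_hd[hd_early] = "early"
    dyn_hd[hd_late] = "late"
    dyn_hd[hd_persistent] = "persistent"
    dyn_hd[ld_induced_ai] = "persistent"   # AI-style respond under HD too
    dyn_ldhd = dyn_hd.copy()
    dyn_ldhd[ld_induced_ps] = "persistent"  # raised at both LD+HD times
    dyn_ldhd[ld_reduced] = "persistent"     # lowered at both LD+HD times

    # reshufflers: change dynamics class between the arms
    for i, p in enumerate(resh_early):
        if i % 2 == 0:  # early -> late
            mult.loc[p, ["LDHD3", "LDHD24"]] = [1.0, F]
            dyn_ldhd[p] = "late"
        else:           # early -> persistent
            mult.loc[p, ["LDHD3", "LDHD24"]] = [F, F]
            dyn_ldhd[p] = "persistent"
    for i, p in enumerate(resh_late):
        if i % 2 == 0:  # late -> early
            mult.loc[p, ["LDHD3", "LDHD24"]] = [F, 1.0]
            dyn_ldhd[p] = "early"
        else:           # late -> persistent
            mult.loc[p, ["LDHD3", "LDHD24"]] = [F, F]
            dyn_ldhd[p] = "persistent"

    # readouts: LD-silent, sub-threshold HD response, boosted under LD+HD
    # (the LD+HD multiplier clears the screen threshold, so readouts show
    # persistent dynamics in the primed arm)
    mult.loc[readouts, ["HD3", "HD24"]] = rhd
    mult.loc[readouts, ["LDHD3", "LDHD24"]] = rhd * rb
    if rhd * rb >= 2.0:
        dyn_ldhd[readouts] = "persistent"

    baseline = 2.0 ** rng.normal(
        spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_probes
    )
    cols, conds, reps = [], {}, {}
    data = {}
    for cond in CONDITIONS:
        for rep in range(1, spec.n_replicates + 1):
            name = f"{cond}_r{rep}"
            noise = 2.0 ** (spec.sigma_log2 * rng.standard_normal(spec.n_probes))
            data[name] = baseline * mult[cond].to_numpy() * noise
            cols.append(name)
            conds[name] = cond
            reps[name] = rep
    values = pd.DataFrame(data, index=probes, columns=cols)

    calls = pd.DataFrame("P", index=probes, columns=cols)
    calls.loc[absent] = "A"

    ld_class = pd.Series("LD-silent", index=probes)
    ld_class[ld_induced] = "LD-induced"
    ld_class[ld_reduced] = "LD-reduced"
    roles = pd.DataFrame(
        {
            "PS-regulator": probes.isin(ld_induced_ps),
            "AI-regulator": probes.isin(ld_induced_ai),
            "SD-suppressor": probes.isin(ld_reduced),
            "HD-partner": dyn_hd.ne("silent").to_numpy()
            & ld_class.eq("LD-silent").to_numpy(),
        },
        index=probes,
    )
    truth = GroundTruth(
        ld_class=ld_class,
        dynamics_hd=dyn_hd,
        dynamics_ldhd=dyn_ldhd,
        roles=roles,
        readouts=readouts,
        absent=absent,
        reshufflers=resh_early.append(resh_late),
        symbols=symbols,
        spec=spec,
    )
    mat = ExpressionMatrix(values, conds, reps, calls=calls, symbols=symbols)
    return mat, truth


@dataclass
class PlantedNetwork:
    """A signed network with known recoverable priming motifs."""

    graph: SignedGraph
    motifs: list[tuple[str, str, str, str]]  # (mechanism, x1, x2, x3)
    roles: dict[str, set[str]]
    readouts: list[str]


def generate_network(
    truth: GroundTruth,
    n_ps: int = 3,
    n_ai: int = 2,
    n_sd: int = 2,
    n_decoys: int = 6,
    seed: int = 0,
    readout_name: str = "READOUT1",
) -> PlantedNetwork:
    """Plant PS/AI/SD motifs on the ground-truth role genes.

    Every planted motif is recoverable by the motif matcher; decoy edges
    are added that violate the sign templates (a PS-style pair where the
    partner inhibits, an SD-style pair where the suppressor activates)
    plus random edges between null genes.  One planted motif per
    mechanism is routed through an intermediate node to exercise
    indirect (length-2) paths.
    """
    rng = np.random.default_rng(seed)
    g = SignedGraph()
    sym = truth.symbols
    ps_regs = [sym[p] for p in truth.roles.index[truth.roles["PS-regulator"]]]
    ai_regs = [sym[p] for p in truth.roles.index[truth.roles["AI-regulator"]]]
    sd_sups = [sym[p] for p in truth.roles.index[truth.roles["SD-suppressor"]]]
    partners = [sym[p] for p in truth.roles.index[truth.roles["HD-partner"]]]
    if min(len(ps_regs), len(ai_regs), len(sd_sups)) == 0 or len(partners) < (
        n_ps + n_ai + n_sd
    ):
        raise ValueError("ground truth lacks enough role genes")

    roles: dict[str, set[str]] = {}
    motifs: list[tuple[str, str, str, str]] = []
    p_iter = iter(partners)

    def add_role(gene, role):
        roles.setdefault(gene, set()).add(role)

    for i in range(n_ps):
        x1, x2 = ps_regs[i % len(ps_regs)], next(p_iter)
        if i == 0:  # indirect path through an intermediate
            g.add_edge(x1, f"PS_VIA_{i}", 1)
            g.add_edge(f"PS_VIA_{i}", readout_name, 1, "indirect")
        else:
            g.add_edge(x1, readout_name, 1)
        g.add_edge(x2, readout_name, 1)
        add_role(x1, "PS-regulator")
        add_role(x2, "HD-partner")
        motifs.append(("PS", x1, x2, readout_name))
    for i in range(n_ai):
        x1, x2 = ai_regs[i % len(ai_regs)], next(p_iter)
        g.add_edge(x1, readout_name, 1)
        if i == 0:
            g.add_edge(x2, f"AI_VIA_{i}", 1)
            g.add_edge(f"AI_VIA_{i}", readout_name, -1, "indirect")
        else:
            g.add_edge(x2, readout_name, -1)
        add_role(x1, "AI-regulator")
        add_role(x2, "HD-partner")
        motifs.append(("AI", x1, x2, readout_name))
    for i in range(n_sd):
        x1, x2 = sd_sups[i % len(sd_sups)], next(p_iter)
        g.add_edge(x1, readout_name, -1)
        g.add_edge(x2, readout_name, 1)
        add_role(x1, "SD-suppressor")
        add_role(x2, "HD-partner")
        motifs.append(("SD", x1, x2, readout_name))

    # decoys: a suppressor-role gene wired with an activating edge to the
    # readout (violating the SD sign template, so the matcher must not
    # emit it) plus a ring of null genes
    decoy_sup = sd_sups[n_sd] if len(sd_sups) > n_sd else "DECOY_SUP"
    g.add_edge(decoy_sup, readout_name, 1)
    add_role(decoy_sup, "SD-suppressor")
    nulls = [f"NULL{i}" for i in range(n_decoys)]
    for i, a in enumerate(nulls):
        g.add_edge(a, nulls[(i + 1) % len(nulls)], int(rng.choice([1, -1])))

    return PlantedNetwork(
        graph=g,
        motifs=sorted(set(motifs)),
        roles=roles,
        readouts=[readout_name],
    )


# ---------------------------------------------------------------------------
# Three-node exemplars, one per mechanism
# ---------------------------------------------------------------------------

def _params(k, gamma, w, K) -> TriNodeParams:
    return TriNodeParams(k=np.array(k), gamma=np.array(gamma), w=w, K=K)


def generate_trinode_exemplars() -> dict[str, tuple[TriNodeTopology, TriNodeParams]]:
    """Hand-constructed parameter sets, one per priming mechanism.

    - ``PS``: two activating pathways; x1 fast with a high stimulus
      threshold, x2 a slow low-threshold accumulator whose LD-gained
      head start pushes the readout past what HD alone achieves within
      the treatment window.
    - ``AI``: the LD-inducible activator x2 outruns the HD-induced
      inhibitor x1 when pre-induced; without pretreatment the two rise
      together and the readout stays moderate.
    - ``SD``: the suppressor x1 sits high at rest and is lowered by the
      LD-induced x2; with the brake pre-released, the HD response of the
      readout overshoots.

    Each exemplar satisfies the three priming clauses and classifies to
    its intended label.
    """
    ps = _params(
        k=[1.5, 0.008, 1.0],
        gamma=[0.8, 0.002, 3.0],
        w={("S", "x1"): 1.0, ("S", "x2"): 1.0, ("x1", "x3"): 0.4,
           ("x2", "x3"): 3.3, ("x3", "x1"): 0.3},
        K={("S", "x1"): 0.4, ("S", "x2"): 0.015, ("x1", "x3"): 0.35,
           ("x2", "x3"): 0.75, ("x3", "x1"): 0.3},
    )
    ai = _params(  # polished from a search-found activator-induction set
        k=[0.7807, 0.02836, 0.02701],
        gamma=[0.01023, 0.01582, 0.004608],
        w={("S", "x1"): 1.0, ("S", "x2"): 1.0, ("x1", "x3"): 0.7336,
           ("x2", "x3"): 1.141},
        K={("S", "x1"): 0.02292, ("S", "x2"): 0.02927, ("x1", "x3"): 0.07362,
           ("x2", "x3"): 0.971},
    )
    sd = _params(
        k=[1.0, 1.5, 1.0],
        gamma=[0.01, 1.0, 2.0],
        w={("S", "x1"): 1.0, ("S", "x2"): 1.0, ("x1", "x3"): 4.0,
           ("x2", "x3"): 3.0, ("x2", "x1"): 6.0},
        K={("S", "x1"): 3.0, ("S", "x2"): 0.035, ("x1", "x3"): 0.5,
           ("x2", "x3"): 1.0, ("x2", "x1"): 0.2},
    )
    return {
        "PS": (CANONICAL_TOPOLOGIES["PS"], ps),
        "AI": (CANONICAL_TOPOLOGIES["AI"], ai),
        "SD": (CANONICAL_TOPOLOGIES["SD"], sd),
    }
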