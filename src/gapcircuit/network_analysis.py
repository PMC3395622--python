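"""From parameter ensembles to regulatory biology.

Fitted circuits are read out as networks: each regulatory weight is
classified as repressing, absent or activating with a cut-off of 0.005
below which an interaction is considered absent.  Ensembles are summarised
as number triplets (repressing / none / activating) per interaction with a
strict-majority consensus.

Interactions between overlapping expression domains are compared by their
*net effect*: the regulatory weight multiplied by the regulator's
concentration, integrated (here: averaged per nucleus-time) over the region
of overlap.  Anterior domain shifts require the posterior-to-anterior net
effect to be repressive and stronger than the reciprocal one.

The mechanism report computes, over a QC-passed ensemble, the fractions of
circuits exhibiting: alternating cushions (mutual repression of hb/kni and
Kr/gt), per-gene auto-activation, the three shift net effects (posterior Hb
represses gt, Gt represses kni, Kni represses Kr), the direction of the
hb/Kr net repression, activation by the maternal gradients (Bcd on all four
gap genes, Cad on gt and kni) and terminal inhibition (Hkb on hb, Tll on
the other three gap genes).

The reduced-data harness emulates sparser experiments: random elimination
of individual boundary observations (always retaining at least one per
boundary and time point) and random removal of intermediate time classes
(the initial and final time classes are never removed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit_model import CircuitParameters
from .simulator import Trajectory

__all__ = [
    "InteractionSummary",
    "MechanismReport",
    "classify_interaction",
    "interaction_summary",
    "overlap_region",
    "net_effect",
    "mechanism_report",
    "reduce_boundaries",
    "reduce_timeclasses",
]

REGULATORY_CUTOFF = 0.005

CATEGORIES = ("repressing", "none", "activating")


def classify_interaction(weight: float, cutoff: float = REGULATORY_CUTOFF) -> str:
    """Regulatory category of a weight: repressing iff w < -cutoff,
    activating iff w > cutoff, otherwise none (boundary values -> none)."""
    w = float(weight)
    if not np.isfinite(w):
        raise ValueError("weight must be finite")
    if w < -cutoff:
        return "repressing"
    if w > cutoff:
        return "activating"
    return "none"


@dataclass
class InteractionSummary:
    """Ensemble triplets (n_repressing, n_none, n_activating) per edge."""

    triplets: dict   # (regulator, target) -> (n_rep, n_none, n_act)
    consensus: dict  # (regulator, target) -> category or "ambiguous"
    ensemble_size: int


def _weight_of(params: CircuitParameters, regulator: str, target: str) -> float:
    spec = params.spec
    a = spec.gene_index(target)
    if regulator in spec.gap_genes:
        return float(params.W[spec.gene_index(regulator), a])
    return float(params.E[spec.input_index(regulator), a])


def interaction_summary(ensemble, cutoff: float = REGULATORY_CUTOFF
                        ) -> InteractionSummary:
    """Triplet counts and strict-majority consensus over an ensemble of
    fitted parameter sets (order-invariant)."""
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("empty ensemble")
    spec = ensemble[0].spec
    edges = [(r, t) for r in spec.gap_genes + spec.external_inputs
             for t in spec.gap_genes]
    triplets, consensus = {}, {}
    n = len(ensemble)
    for edge in edges:
        counts = {c: 0 for c in CATEGORIES}
        for params in ensemble:
            counts[classify_interaction(_weight_of(params, *edge), cutoff)] += 1
        trip = (counts["repressing"], counts["none"], counts["activating"])
        triplets[edge] = trip
        winner = max(CATEGORIES, key=lambda c: counts[c])
        consensus[edge] = winner if counts[winner] * 2 > n else "ambiguous"
    return InteractionSummary(triplets=triplets, consensus=consensus,
                              ensemble_size=n)


# ---------------------------------------------------------------------------
# Net effects over overlap regions
# ---------------------------------------------------------------------------


def overlap_region(trajectory: Trajectory, gene_a: str, gene_b: str,
                   time: float, spec=None, threshold: float = 0.1
                   ) -> np.ndarray:
    """Nuclei (lattice columns) where both genes are expressed at a time.

    A gene counts as expressed where it exceeds ``threshold`` times its own
    slice maximum.  For genes with multiple domains the posterior-most
    contiguous run of the joint region is returned (the relevant one for
    the shift analysis); for single-domain profiles this is the full
    overlap.  May be empty.
    """
    snap = trajectory.at(time)
    if spec is None:
        raise ValueError("spec required to index genes")
    va = snap.values[spec.gene_index(gene_a)]
    vb = snap.values[spec.gene_index(gene_b)]
    mask = np.ones_like(va, dtype=bool)
    for v in (va, vb):
        vmax = v.max()
        mask &= (v > threshold * vmax) if vmax > 0 else False
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return idx
    # posterior-most contiguous run
    breaks = np.flatnonzero(np.diff(idx) > 1)
    start = idx[breaks[-1] + 1] if len(breaks) else idx[0]
    return idx[idx >= start]


def net_effect(trajectory: Trajectory, params: CircuitParameters,
               regulator: str, target: str, region, times) -> float:
    """Net effect of regulator on target over a region and set of times.

    The regulatory weight multiplied by the regulator's concentration,
    averaged per nucleus-time over the overlap region (normalisation makes
    regions of different sizes comparable).  Negative = net repression.
    """
    region = np.asarray(region, dtype=int)
    times = list(times)
    if region.size == 0:
        raise ValueError("empty overlap region")
    if not times:
        raise ValueError("no times given")
    w = _weight_of(params, regulator, target)
    spec = params.spec
    total = 0.0
    for t in times:
        snap = trajectory.at(t)
        if regulator in spec.gap_genes:
            conc = snap.values[spec.gene_index(regulator), region]
        else:
            raise ValueError(
                "net effects are defined for gap-gap interactions here"
            )
        total += float(np.sum(conc))
    return w * total / (len(times) * region.size)


# ---------------------------------------------------------------------------
# Mechanism report
# ---------------------------------------------------------------------------

#: (posterior regulator, anterior target) pairs of the shift mechanism.
SHIFT_PAIRS = (("hb", "gt"), ("gt", "kni"), ("kni", "Kr"))

#: Non-overlapping domain pairs with mutual repression (alternating cushions).
CUSHION_PAIRS = (("hb", "kni"), ("Kr", "gt"))


@dataclass
class MechanismReport:
    """Fractions of selected circuits exhibiting each regulatory mechanism."""

    alternating_cushions: float
    auto_activation: dict          # gene -> fraction
    shifts: dict                   # (regulator, target) -> fraction
    kr_represses_hb_net: float     # direction of the hb/Kr net interaction
    bcd_cad_activation: float
    tll_hkb_inhibition: float
    ensemble_size: int

    def as_dict(self) -> dict:
        return {
            "alternating_cushions": self.alternating_cushions,
            "auto_activation": dict(self.auto_activation),
            "shifts": {f"{r}->{t}": f for (r, t), f in self.shifts.items()},
            "kr_represses_hb_net": self.kr_represses_hb_net,
            "bcd_cad_activation": self.bcd_cad_activation,
            "tll_hkb_inhibition": self.tll_hkb_inhibition,
            "ensemble_size": self.ensemble_size,
        }


def _circuit_mechanisms(params: CircuitParameters,
                        trajectory: Trajectory | None,
                        cutoff: float,
                        times=None,
                        overlap_threshold: float = 0.1) -> dict:
    spec = params.spec
    rep = lambda r, t: classify_interaction(_weight_of(params, r, t),
                                            cutoff) == "repressing"
    act = lambda r, t: classify_interaction(_weight_of(params, r, t),
                                            cutoff) == "activating"

    out = {}
    out["alternating_cushions"] = all(
        rep(a, b) and rep(b, a) for a, b in CUSHION_PAIRS
    )
    out["auto_activation"] = {g: act(g, g) for g in spec.gap_genes}

    shifts = {}
    kr_hb = None
    if trajectory is not None:
        if times is None:
            times = [t for t in trajectory.times
                     if trajectory.at(t).lattice.stage != "C13"]
        for reg, tgt in SHIFT_PAIRS:
            vals = []
            for t in times:
                region = overlap_region(trajectory, reg, tgt, t, spec=spec,
                                        threshold=overlap_threshold)
                if region.size == 0:
                    continue
                fwd = net_effect(trajectory, params, reg, tgt, region, [t])
                back = net_effect(trajectory, params, tgt, reg, region, [t])
                vals.append((fwd, back))
            if vals:
                fwd = float(np.mean([v[0] for v in vals]))
                back = float(np.mean([v[1] for v in vals]))
                shifts[(reg, tgt)] = fwd < 0 and fwd < back
            else:
                shifts[(reg, tgt)] = False
        vals = []
        for t in times:
            region = overlap_region(trajectory, "hb", "Kr", t, spec=spec,
                                    threshold=overlap_threshold)
            if region.size == 0:
                continue
            kr_on_hb = net_effect(trajectory, params, "Kr", "hb", region, [t])
            hb_on_kr = net_effect(trajectory, params, "hb", "Kr", region, [t])
            vals.append((kr_on_hb, hb_on_kr))
        if vals:
            kr_on_hb = float(np.mean([v[0] for v in vals]))
            hb_on_kr = float(np.mean([v[1] for v in vals]))
            kr_hb = kr_on_hb < 0 and kr_on_hb < hb_on_kr
    out["shifts"] = shifts
    out["kr_represses_hb_net"] = bool(kr_hb) if kr_hb is not None else False

    if "bcd" in spec.external_inputs:
        out["bcd_cad_activation"] = (
            all(act("bcd", g) for g in spec.gap_genes)
            and act("cad", "gt") and act("cad", "kni")
        )
        out["tll_hkb_inhibition"] = (
            rep("hkb", "hb")
            and all(rep("tll", g) for g in spec.gap_genes if g != "hb")
        )
    else:
        out["bcd_cad_activation"] = False
        out["tll_hkb_inhibition"] = False
    return out


def mechanism_report(ensemble, trajectories=None,
                     cutoff: float = REGULATORY_CUTOFF,
                     times=None, overlap_threshold: float = 0.1
                     ) -> MechanismReport:
    """Mechanism fractions over an ensemble of (QC-passed) circuits.

    ``ensemble`` is a list of CircuitParameters (or FitResults, from which
    parameters are taken); ``trajectories`` the matching simulated
    trajectories, required for the net-effect (shift) mechanisms.  The
    report over an ensemble equals the average of per-circuit reports.
    """
    params_list = [getattr(e, "params", e) for e in ensemble]
    if not params_list:
        raise ValueError("empty ensemble")
    if trajectories is None:
        trajectories = [None] * len(params_list)
    per = [
        _circuit_mechanisms(p, tr, cutoff, times, overlap_threshold)
        for p, tr in zip(params_list, trajectories)
    ]
    n = len(per)
    genes = params_list[0].spec.gap_genes
    return MechanismReport(
        alternating_cushions=sum(m["alternating_cushions"] for m in per) / n,
        auto_activation={
            g: sum(m["auto_activation"][g] for m in per) / n for g in genes
        },
        shifts={
            pair: sum(m["shifts"].get(pair, False) for m in per) / n
            for pair in SHIFT_PAIRS
        },
        kr_represses_hb_net=sum(m["kr_represses_hb_net"] for m in per) / n,
        bcd_cad_activation=sum(m["bcd_cad_activation"] for m in per) / n,
        tll_hkb_inhibition=sum(m["tll_hkb_inhibition"] for m in per) / n,
        ensemble_size=n,
    )


# ---------------------------------------------------------------------------
# Reduced-data harness
# ---------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def reduce_boundaries(annotations, fraction: float, seed: int) -> list:
    """Randomly eliminate individual boundary observations.

    Per (gene, time class, boundary id) group of size n, retain
    max(1, round(fraction * n)) observations drawn uniformly without
    replacement (round = half away from zero) -- at least one data point is
    always retained to avoid artifactual fusion or ectopic extension of
    domains.  Deterministic per seed.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    groups: dict = {}
    for b in annotations:
        groups.setdefault((b.gene, b.time_class, b.boundary_id), []).append(b)
    out = []
    for key in sorted(groups):
        group = groups[key]
        n_keep = max(1, _round_half_away(fraction * len(group)))
        if n_keep >= len(group):
            out.extend(group)
        else:
            idx = rng.choice(len(group), size=n_keep, replace=False)
            out.extend(group[i] for i in sorted(idx))
    return out


def reduce_timeclasses(annotations, k: int, seed: int,
                       first: str | None = None, last: str | None = None
                       ) -> list:
    """Randomly keep only k of the time classes (k of 9 on the standard
    schedule).

    The initial and final time classes are never removed; the remaining
    classes are eliminated uniformly at random from the intermediate ones.
    First/last default to the first and last time classes present in the
    annotations (C13 and T8 on the standard schedule).  Deterministic per
    seed.
    """
    order = list(dict.fromkeys(b.time_class for b in annotations))
    if first is None:
        first = order[0]
    if last is None:
        last = order[-1]
    if not (3 <= k <= max(len(order), 3)):
        raise ValueError(f"k must be in [3, {len(order)}], got {k}")
    rng = np.random.default_rng(seed)
    middle = [tc for tc in order if tc not in (first, last)]
    keep_middle = sorted(
        rng.choice(len(middle), size=k - 2, replace=False).tolist()
    )
    kept = {first, last} | {middle[i] for i in keep_middle}
    return [b for b in annotations if b.time_class in kept]
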