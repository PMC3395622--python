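"""Static structure of gap gene circuits.

A gene circuit models a row of syncytial blastoderm nuclei along the
antero-posterior (A-P) axis of the early Drosophila embryo.  Each nucleus
runs identical regulatory dynamics over a set of *trunk gap genes*
(by default hb, Kr, gt, kni) driven by *external inputs* -- regulators that
are not themselves regulated by the trunk gap genes (maternal gradients
Bcd and Cad, terminal gap genes Tll and Hkb).

This module defines the network specification, the parameter vector with
its fixed-value masks, the nucleus lattice along the A-P axis, and the
sigmoid regulation-expression function.
"""

from __future__ import annotations

import configparser
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAP_GENES",
    "EXTERNAL_INPUTS",
    "TRUNK_AP_RANGE",
    "GeneNetworkSpec",
    "ParameterMask",
    "CircuitParameters",
    "NucleusLattice",
    "DivisionSchedule",
    "build_lattice",
    "regulation_function",
    "total_input",
    "count_state_variables",
    "DATA_TIMES",
]

#: Canonical gene orderings used everywhere, including file I/O.
GAP_GENES = ("hb", "Kr", "gt", "kni")
EXTERNAL_INPUTS = ("bcd", "cad", "tll", "hkb")

#: Trunk region of the embryo covered by the models, in % A-P position.
TRUNK_AP_RANGE = (35.0, 87.0)

#: Threshold parameter representing uniformly distributed maternal factors,
#: fixed for all gap genes during fitting.
DEFAULT_H = -2.5

#: Number of nuclei along the whole A-P axis per cleavage cycle stage.
STAGE_N_AXIS = {"C13": 50, "C14A": 100}

#: Times (minutes from early C13) at which expression data are available.
DATA_TIMES = {
    "C13": 10.550,
    "T1": 24.225,
    "T2": 30.475,
    "T3": 36.725,
    "T4": 42.975,
    "T5": 49.225,
    "T6": 55.475,
    "T7": 61.725,
    "T8": 67.975,
}

TIME_CLASSES = tuple(DATA_TIMES)


@dataclass(frozen=True)
class GeneNetworkSpec:
    """Genes, external inputs and the modelled A-P range of a circuit."""

    gap_genes: tuple[str, ...] = GAP_GENES
    external_inputs: tuple[str, ...] = EXTERNAL_INPUTS
    ap_range: tuple[float, float] = TRUNK_AP_RANGE

    def __post_init__(self) -> None:
        genes = tuple(self.gap_genes)
        inputs = tuple(self.external_inputs)
        object.__setattr__(self, "gap_genes", genes)
        object.__setattr__(self, "external_inputs", inputs)
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate gap gene identifiers: {genes}")
        if len(set(inputs)) != len(inputs):
            raise ValueError(f"duplicate external input identifiers: {inputs}")
        if set(genes) & set(inputs):
            raise ValueError(
                "gap genes and external inputs must be disjoint: "
                f"{set(genes) & set(inputs)}"
            )
        lo, hi = self.ap_range
        if not (0.0 <= lo < hi <= 100.0):
            raise ValueError(f"invalid ap_range {self.ap_range}")

    @property
    def n_genes(self) -> int:
        return len(self.gap_genes)

    @property
    def n_inputs(self) -> int:
        return len(self.external_inputs)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gap_genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gap gene {gene!r}") from None

    def input_index(self, name: str) -> int:
        try:
            return self.external_inputs.index(name)
        except ValueError:
            raise KeyError(f"unknown external input {name!r}") from None

    @classmethod
    def from_config(cls, path) -> "GeneNetworkSpec":
        """Read a network spec from an INI-style config file.

        Recognised keys (section ``[network]``): ``gap_genes``,
        ``external_inputs`` (comma-separated) and ``ap_range`` ("lo, hi").
        """
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        sec = cp["network"] if cp.has_section("network") else cp["DEFAULT"]
        kwargs = {}
        if "gap_genes" in sec:
            kwargs["gap_genes"] = tuple(
                g.strip() for g in sec["gap_genes"].split(",") if g.strip()
            )
        if "external_inputs" in sec:
            kwargs["external_inputs"] = tuple(
                g.strip() for g in sec["external_inputs"].split(",") if g.strip()
            )
        if "ap_range" in sec:
            lo, hi = (float(v) for v in sec["ap_range"].split(","))
            kwargs["ap_range"] = (lo, hi)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Parameter vector and masks
# ---------------------------------------------------------------------------

#: Parameter blocks in serialization order.
PARAM_BLOCKS = ("W", "E", "R", "D", "lam", "h")


def _block_shape(block: str, spec: GeneNetworkSpec) -> tuple[int, ...]:
    g, m = spec.n_genes, spec.n_inputs
    return {
        "W": (g, g),
        "E": (m, g),
        "R": (g,),
        "D": (g,),
        "lam": (g,),
        "h": (g,),
    }[block]


@dataclass
class ParameterMask:
    """Per-entry fixed-value masks for a circuit's parameters.

    Each block holds an array of the block's shape where NaN marks a *free*
    entry and any finite value marks an entry *fixed* at that value.  Masked
    entries never change through the fitting API.
    """

    W: np.ndarray
    E: np.ndarray
    R: np.ndarray
    D: np.ndarray
    lam: np.ndarray
    h: np.ndarray

    @classmethod
    def all_free(cls, spec: GeneNetworkSpec) -> "ParameterMask":
        return cls(
            **{b: np.full(_block_shape(b, spec), np.nan) for b in PARAM_BLOCKS}
        )

    @classmethod
    def default(cls, spec: GeneNetworkSpec) -> "ParameterMask":
        """Default fitting mask: h fixed at -2.5 for all gap genes, and all
        Hkb->target entries of E fixed to 0 except Hkb->hb."""
        mask = cls.all_free(spec)
        mask.h[:] = DEFAULT_H
        if "hkb" in spec.external_inputs:
            m = spec.input_index("hkb")
            for gene in spec.gap_genes:
                if gene != "hb":
                    mask.E[m, spec.gene_index(gene)] = 0.0
        return mask

    def block(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @classmethod
    def from_config(cls, path, spec: GeneNetworkSpec,
                    base: "ParameterMask | None" = None) -> "ParameterMask":
        """Read per-entry mask overrides from an INI-style config file.

        Section ``[mask]`` keys name entries as ``h.<gene>``, ``R.<gene>``,
        ``W.<regulator>.<target>`` or ``E.<input>.<target>`` (or a whole
        block, e.g. ``h``); values are a number (fix at that value) or
        ``free``.  Overrides are applied on top of ``base`` (default: the
        standard mask with h = -2.5 and the Hkb interactions zeroed).
        """
        cp = configparser.ConfigParser()
        cp.optionxform = str  # gene names are case-sensitive (Kr vs kr)
        with open(path) as fh:
            cp.read_file(fh)
        mask = (base or cls.default(spec)).copy()
        if not cp.has_section("mask"):
            return mask
        for key, raw in cp["mask"].items():
            parts = key.split(".")
            block = {"w": "W", "e": "E", "r": "R", "d": "D",
                     "lam": "lam", "h": "h"}.get(parts[0], parts[0])
            value = np.nan if raw.strip().lower() == "free" else float(raw)
            if len(parts) == 1:
                mask.fix(block, value)
            elif block in ("W", "E"):
                reg = (spec.gene_index(parts[1]) if block == "W"
                       else spec.input_index(parts[1]))
                mask.fix(block, value, regulator=reg,
                         target=spec.gene_index(parts[2]))
            else:
                mask.fix(block, value, target=spec.gene_index(parts[1]))
        return mask

    def fix(self, block: str, value: float, regulator=None, target=None) -> None:
        """Fix a single entry (or a whole block when no index is given)."""
        arr = self.block(block)
        if regulator is None and target is None:
            arr[...] = value
        elif arr.ndim == 1:
            arr[target] = value
        else:
            arr[regulator, target] = value

    def copy(self) -> "ParameterMask":
        return ParameterMask(**{b: self.block(b).copy() for b in PARAM_BLOCKS})


@dataclass
class CircuitParameters:
    """The full parameter vector theta of a gene circuit.

    Attributes
    ----------
    W : (G, G) array
        Gap->gap regulatory weights; ``W[b, a]`` is the effect of regulator
        ``b`` on target gene ``a`` (dimensionless).
    E : (M, G) array
        External-input weights; ``E[m, a]`` is the effect of input ``m`` on
        gap gene ``a``.
    R : (G,) array
        Maximum synthesis rates (concentration/min), strictly positive.
    D : (G,) array
        Diffusion rates at cycle-13 nucleus spacing (1/min), non-negative.
    lam : (G,) array
        Linear decay rates (1/min), strictly positive.
    h : (G,) array
        Threshold parameters (dimensionless).
    mask : ParameterMask
        Fixed-value masks; applied on construction and after every mutation
        through the fitting API.
    """

    spec: GeneNetworkSpec
    W: np.ndarray
    E: np.ndarray
    R: np.ndarray
    D: np.ndarray
    lam: np.ndarray
    h: np.ndarray
    mask: ParameterMask = None

    def __post_init__(self) -> None:
        for b in PARAM_BLOCKS:
            arr = np.asarray(getattr(self, b), dtype=float)
            want = _block_shape(b, self.spec)
            if arr.shape != want:
                raise ValueError(f"block {b}: shape {arr.shape}, expected {want}")
            setattr(self, b, arr)
        if self.mask is None:
            self.mask = ParameterMask.all_free(self.spec)
        self.apply_mask()
        self.validate()

    def validate(self) -> None:
        if not np.all(self.R > 0):
            raise ValueError("synthesis rates R must be > 0")
        if not np.all(self.D >= 0):
            raise ValueError("diffusion rates D must be >= 0")
        if not np.all(self.lam > 0):
            raise ValueError("decay rates lam must be > 0")
        for b in PARAM_BLOCKS:
            if not np.all(np.isfinite(getattr(self, b))):
                raise ValueError(f"non-finite values in block {b}")

    def block(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def apply_mask(self) -> None:
        for b in PARAM_BLOCKS:
            m = self.mask.block(b)
            fixed = ~np.isnan(m)
            arr = self.block(b)
            arr[fixed] = m[fixed]

    # -- flat free-parameter view used by optimizers and identifiability ----

    def free_entries(self) -> list[tuple[str, tuple]]:
        """(block, index) pairs of free parameters in canonical order."""
        out = []
        for b in PARAM_BLOCKS:
            m = self.mask.block(b)
            for idx in np.ndindex(m.shape):
                if np.isnan(m[idx]):
                    out.append((b, idx))
        return out

    def free_labels(self) -> list[str]:
        """Human-readable labels, e.g. ``W[hb->Kr]`` or ``R[gt]``."""
        labels = []
        genes, inputs = self.spec.gap_genes, self.spec.external_inputs
        for b, idx in self.free_entries():
            if b == "W":
                labels.append(f"W[{genes[idx[0]]}->{genes[idx[1]]}]")
            elif b == "E":
                labels.append(f"E[{inputs[idx[0]]}->{genes[idx[1]]}]")
            else:
                labels.append(f"{b}[{genes[idx[0]]}]")
        return labels

    def to_vector(self) -> np.ndarray:
        return np.array([self.block(b)[idx] for b, idx in self.free_entries()])

    def with_vector(self, vec: np.ndarray) -> "CircuitParameters":
        """A copy with free parameters replaced by ``vec`` (masked entries
        keep their fixed values exactly)."""
        entries = self.free_entries()
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(entries),):
            raise ValueError(
                f"expected {len(entries)} free parameters, got {vec.shape}"
            )
        new = self.copy()
        for (b, idx), val in zip(entries, vec):
            new.block(b)[idx] = val
        new.apply_mask()
        new.validate()
        return new

    @property
    def n_free(self) -> int:
        return len(self.free_entries())

    def copy(self) -> "CircuitParameters":
        return CircuitParameters(
            spec=self.spec,
            **{b: self.block(b).copy() for b in PARAM_BLOCKS},
            mask=self.mask.copy(),
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        """Serialize with explicit gene/input labels (never positional only)."""
        genes, inputs = self.spec.gap_genes, self.spec.external_inputs

        def mat(arr, rows):
            return {r: {g: arr[i, j] for j, g in enumerate(genes)}
                    for i, r in enumerate(rows)}

        def vec(arr):
            return {g: arr[j] for j, g in enumerate(genes)}

        doc = {
            "gap_genes": list(genes),
            "external_inputs": list(inputs),
            "ap_range": list(self.spec.ap_range),
            "W": mat(self.W, genes),
            "E": mat(self.E, inputs),
            "R": vec(self.R),
            "D": vec(self.D),
            "lam": vec(self.lam),
            "h": vec(self.h),
            "mask": {
                "W": mat(self.mask.W, genes),
                "E": mat(self.mask.E, inputs),
                "R": vec(self.mask.R),
                "D": vec(self.mask.D),
                "lam": vec(self.mask.lam),
                "h": vec(self.mask.h),
            },
        }
        text = json.dumps(doc, indent=1, default=lambda x: None if np.isnan(x) else float(x))
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CircuitParameters":
        if isinstance(source, (str, bytes)) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        spec = GeneNetworkSpec(
            gap_genes=tuple(doc["gap_genes"]),
            external_inputs=tuple(doc["external_inputs"]),
            ap_range=tuple(doc.get("ap_range", TRUNK_AP_RANGE)),
        )
        genes, inputs = spec.gap_genes, spec.external_inputs

        def parse(node, rows):
            if rows is None:
                return np.array(
                    [np.nan if node[g] is None else node[g] for g in genes]
                )
            return np.array(
                [[np.nan if node[r][g] is None else node[r][g] for g in genes]
                 for r in rows]
            )

        mask = ParameterMask(
            W=parse(doc["mask"]["W"], genes),
            E=parse(doc["mask"]["E"], inputs),
            R=parse(doc["mask"]["R"], None),
            D=parse(doc["mask"]["D"], None),
            lam=parse(doc["mask"]["lam"], None),
            h=parse(doc["mask"]["h"], None),
        )
        return cls(
            spec=spec,
            W=parse(doc["W"], genes),
            E=parse(doc["E"], inputs),
            R=parse(doc["R"], None),
            D=parse(doc["D"], None),
            lam=parse(doc["lam"], None),
            h=parse(doc["h"], None),
            mask=mask,
        )


# ---------------------------------------------------------------------------
# Nucleus lattice
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucleusLattice:
    """Spatial discretization: contiguous nuclei inside the modelled A-P range.

    Nucleus ``j`` of a stage with ``n_axis`` nuclei along the whole axis
    spans ``[100*j/n_axis, 100*(j+1)/n_axis)`` % A-P (half-open); it belongs
    to the lattice iff its span intersects the closed ``ap_range`` interval.
    """

    stage: str
    n_axis: int
    indices: np.ndarray  # contiguous axis indices inside ap_range
    ap_range: tuple[float, float]

    @property
    def n_nuclei(self) -> int:
        return len(self.indices)

    @property
    def width(self) -> float:
        """Nucleus width in % A-P."""
        return 100.0 / self.n_axis

    @property
    def positions(self) -> np.ndarray:
        """% A-P centre of each nucleus."""
        return (self.indices + 0.5) * self.width

    def column_of(self, axis_indices) -> np.ndarray:
        """Lattice column(s) for given axis indices."""
        cols = np.asarray(axis_indices) - self.indices[0]
        if np.any(cols < 0) or np.any(cols >= self.n_nuclei):
            raise KeyError(f"axis indices {axis_indices} outside lattice")
        return cols


def build_lattice(stage: str, ap_range=TRUNK_AP_RANGE, n_axis: int | None = None
                  ) -> NucleusLattice:
    """Build the nucleus lattice for a cleavage-cycle stage.

    Parameters
    ----------
    stage : {"C13", "C14A"} or any label when ``n_axis`` is given
        Determines the number of nuclei along the whole axis (50 at C13,
        100 at C14A) unless ``n_axis`` overrides it (toy lattices).
    ap_range : (lo, hi)
        Modelled region in % A-P position, 0 = anterior pole.
    """
    lo, hi = float(ap_range[0]), float(ap_range[1])
    if not (0.0 <= lo < hi <= 100.0):
        raise ValueError(f"ap_range {ap_range} outside [0, 100]")
    if n_axis is None:
        try:
            n_axis = STAGE_N_AXIS[stage]
        except KeyError:
            raise ValueError(f"unknown stage {stage!r}") from None
    w = 100.0 / n_axis
    if hi - lo < w:
        raise ValueError(
            f"ap_range {ap_range} narrower than one nucleus "
            f"({w:.3g}% A-P) at stage {stage}"
        )
    # include j iff [j*w, (j+1)*w) intersects closed [lo, hi]
    j = np.arange(n_axis)
    keep = (j * w <= hi) & ((j + 1) * w > lo)
    indices = j[keep]
    return NucleusLattice(stage=stage, n_axis=n_axis, indices=indices,
                          ap_range=(lo, hi))


def count_state_variables(spec: GeneNetworkSpec, lattice: NucleusLattice) -> int:
    """Number of ODE state variables: one per (gap gene, nucleus)."""
    return spec.n_genes * lattice.n_nuclei


# ---------------------------------------------------------------------------
# Division schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DivisionSchedule:
    """Hybrid-time structure: interphase / mitosis / instantaneous division.

    The default is the gap-gene schedule: time runs from early C13
    (t = 0 min) to the onset of gastrulation (t = 71.100 min); mitosis
    (synthesis off) spans [16, 21] min and the single nuclear division
    happens instantaneously at 21 min.  ``mitosis=None`` gives a toy
    schedule without division.
    """

    t_start: float = 0.0
    t_end: float = 71.100
    mitosis: tuple[float, float] | None = (16.0, 21.0)
    data_times: dict = field(default_factory=lambda: dict(DATA_TIMES))

    def __post_init__(self) -> None:
        times = list(self.data_times.values())
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("data_times must be strictly increasing")
        if times and not (self.t_start <= times[0] and times[-1] <= self.t_end):
            raise ValueError("data_times must lie within [t_start, t_end]")
        if self.mitosis is not None:
            m0, m1 = self.mitosis
            if not (self.t_start < m0 < m1 < self.t_end):
                raise ValueError("mitosis interval must lie inside (t_start, t_end)")

    @property
    def division_time(self) -> float | None:
        """Instantaneous division at the end of mitosis (None if no division)."""
        return None if self.mitosis is None else self.mitosis[1]

    def time_of(self, time_class: str) -> float:
        return self.data_times[time_class]

    def stage_at(self, t: float) -> str:
        """'C13' before division, 'C14A' at/after (single-division schedule)."""
        div = self.division_time
        return "C13" if div is None or t < div else "C14A"


# ---------------------------------------------------------------------------
# Regulation-expression function
# ---------------------------------------------------------------------------


def regulation_function(u):
    """Sigmoid regulation-expression function g(u) = (u/sqrt(u^2+1) + 1) / 2.

    Strictly increasing with g(0) = 0.5 and limits 0 and 1; point-symmetric
    about 0.5 (g(u) + g(-u) = 1).
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("regulation_function requires finite input")
    out = 0.5 * (u / np.sqrt(u * u + 1.0) + 1.0)
    return out if out.ndim else float(out)


def total_input(gap_concentrations, external_concentrations,
                params: CircuitParameters, gene: str) -> float:
    """Total regulatory input u^a = sum_b w^{ba} v^b + sum_m e^{ma} v^m + h^a."""
    v = np.asarray(gap_concentrations, dtype=float)
    ve = np.asarray(external_concentrations, dtype=float)
    spec = params.spec
    if v.shape != (spec.n_genes,):
        raise ValueError(
            f"gap concentration vector has shape {v.shape}, expected ({spec.n_genes},)"
        )
    if ve.shape != (spec.n_inputs,):
        raise ValueError(
            f"external concentration vector has shape {ve.shape}, "
            f"expected ({spec.n_inputs},)"
        )
    a = spec.gene_index(gene)
    return float(params.W[:, a] @ v + params.E[:, a] @ ve + params.h[a])
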