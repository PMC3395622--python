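"""Building the model-fitting dataset from expression boundary annotations.

The quantification pipeline annotates each expression domain *boundary* with
two anchor points (x0, y0) and (x2, y2) -- the % A-P positions where staining
approaches background and maximum level respectively.  Boundaries are
approximated by a cubic through the anchors with fixed zero derivatives at
both end knots, normalised to run from 0 to 1, and aggregated over embryos by
taking coordinate-wise medians of the anchor points.  Median boundaries per
gene and time class are combined into an integrated normalised profile along
the A-P axis (plateau 1 inside a domain, 0 outside), which is then made
suitable for model fitting by four post-processing steps: (1) binning to 50
(C13) or 100 (C14A) axis bins, (2) linear spatial intensity scaling (x1.0 at
mid-embryo down to x0.5 at the poles), (3) temporal scaling by a quadratic
with a peak of expression during early C14A, and (4) multiplication by a
constant factor of 200 to match the scale of the protein data.

Weighted-least-squares weights approximate the observation that variation
grows with expression level: v = 1/(eps + yhat)^2 on the normalised
(pre-scaling) intensity yhat, penalising ectopic expression where yhat = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._boundary_table import BOUNDARY_TABLE_COLUMNS, MRNA_BOUNDARY_TABLE
from .circuit_model import (
    DATA_TIMES,
    EXTERNAL_INPUTS,
    GeneNetworkSpec,
    NucleusLattice,
    build_lattice,
)

__all__ = [
    "BoundarySpline",
    "ExpressionDataset",
    "boundary_profile",
    "median_boundary",
    "assemble_profile",
    "spatial_scaling_factor",
    "temporal_scaling_factor",
    "postprocess",
    "make_weights",
    "drop_posterior_kr",
    "load_boundary_table_fixture",
    "packaged_boundaries",
    "boundaries_to_tsv",
    "boundaries_from_tsv",
]

RISING = "rising"
FALLING = "falling"


@dataclass(frozen=True)
class BoundarySpline:
    """One rising or falling edge of an expression domain.

    ``x0`` is the anchor where staining approaches background, ``x2`` where
    it approaches maximum; for a rising (anterior, "A") boundary x0 < x2,
    for a falling (posterior, "P") boundary x0 > x2.  Intensities are
    normalised so the spline runs from 0 at x0 to 1 at x2 with zero first
    derivative at both end knots.
    """

    gene: str
    time_class: str
    boundary_id: str
    polarity: str  # "rising" or "falling"
    x0: float
    y0: float
    x2: float
    y2: float
    embryo_id: str = "median"

    def __post_init__(self) -> None:
        if self.polarity not in (RISING, FALLING):
            raise ValueError(f"polarity must be rising/falling, got {self.polarity}")
        if self.x0 == self.x2:
            raise ValueError(f"degenerate boundary {self.boundary_id}: x0 == x2")

    @property
    def x1(self) -> float:
        """Middle control point: average of the anchor x positions."""
        return 0.5 * (self.x0 + self.x2)

    @property
    def span(self) -> tuple[float, float]:
        """(left, right) extent of the boundary in % A-P."""
        return (min(self.x0, self.x2), max(self.x0, self.x2))


def boundary_profile(b: BoundarySpline, x):
    """Normalised intensity of a boundary spline at position(s) x.

    The unique cubic through (x0, 0) and (x2, 1) with zero derivative at
    both end knots; it passes through (x1, 0.5).  Positions outside the
    span are clamped to the nearest anchor value.
    """
    x = np.asarray(x, dtype=float)
    s = np.clip((x - b.x0) / (b.x2 - b.x0), 0.0, 1.0)
    out = s * s * (3.0 - 2.0 * s)
    return out if out.ndim else float(out)


def median_boundary(group) -> BoundarySpline:
    """Median boundary over a group of same-id individual boundaries.

    Anchor points are aggregated coordinate-wise: the median start point
    (x0, y0) and the median end point (x2, y2).  For even group sizes the
    median is the mean of the two central values.
    """
    group = list(group)
    if not group:
        raise ValueError("median_boundary of empty group")
    first = group[0]
    key = (first.gene, first.time_class, first.boundary_id)
    for b in group:
        if (b.gene, b.time_class, b.boundary_id) != key:
            raise ValueError(
                f"mixed boundary ids in group: {key} vs "
                f"{(b.gene, b.time_class, b.boundary_id)}"
            )
        if b.polarity != first.polarity:
            raise ValueError(f"mixed polarity in group {key}")
    return BoundarySpline(
        gene=first.gene,
        time_class=first.time_class,
        boundary_id=first.boundary_id,
        polarity=first.polarity,
        x0=float(np.median([b.x0 for b in group])),
        y0=float(np.median([b.y0 for b in group])),
        x2=float(np.median([b.x2 for b in group])),
        y2=float(np.median([b.y2 for b in group])),
        embryo_id="median",
    )


def profile_at(boundaries, x) -> np.ndarray:
    """Integrated normalised profile of one gene/time class at positions x.

    Boundaries must alternate rising/falling along the axis; the intensity
    is 1 between a rising boundary and the next falling one, 0 outside, and
    follows the boundary splines across their spans.  A profile starting
    with a falling boundary is taken to be a domain extending in from the
    anterior end (level 1 before it); symmetrically at the posterior end.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    bs = sorted(boundaries, key=lambda b: b.span[0])
    for b1, b2 in zip(bs, bs[1:]):
        if b2.span[0] < b1.span[1]:
            raise ValueError(
                "overlapping boundary spans for gene "
                f"{b1.gene}: {b1.boundary_id} and {b2.boundary_id}"
            )
        if b1.polarity == b2.polarity:
            raise ValueError(
                f"boundaries {b1.boundary_id} and {b2.boundary_id} do not "
                "alternate rising/falling"
            )
    out = np.zeros_like(x)
    if not bs:
        return out
    level = 1.0 if bs[0].polarity == FALLING else 0.0
    out[:] = level
    for b in bs:
        left, right = b.span
        inside = (x >= left) & (x < right)
        after = x >= right
        s = (x[inside] - left) / (right - left)
        sval = s * s * (3.0 - 2.0 * s)
        # across its span the profile runs 0 -> 1 (rising) or 1 -> 0
        # (falling) with increasing x, whatever the anchor orientation
        if b.polarity == FALLING:
            out[inside] = 1.0 - sval
            level = 0.0
        else:
            out[inside] = sval
            level = 1.0
        out[after] = level
    return out


def assemble_profile(boundaries, n_axis: int) -> np.ndarray:
    """Profile of one gene/time class sampled at the centres of axis bins.

    ``n_axis`` is the number of nuclei along the whole A-P axis (50 at C13,
    100 at C14A); bin j covers [100j/n_axis, 100(j+1)/n_axis) and the
    profile is evaluated at its centre.  The result is invariant under
    reordering of the boundary list.
    """
    centres = (np.arange(n_axis) + 0.5) * (100.0 / n_axis)
    return profile_at(boundaries, centres)


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------


def spatial_scaling_factor(x):
    """Linear A-P intensity scaling: x1.0 at 50% A-P, x0.5 at both poles."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 100.0):
        raise ValueError("A-P position outside [0, 100]")
    out = 1.0 - np.abs(x - 50.0) / 100.0
    return out if out.ndim else float(out)


#: Anchors of the temporal scaling quadratic: expression onset at early C13,
#: peak around T5, decline by gastrulation.
TEMPORAL_ANCHORS = ((0.0, 0.1), (48.0, 1.0), (71.1, 0.7))


def _temporal_coefficients() -> np.ndarray:
    t = np.array([a[0] for a in TEMPORAL_ANCHORS])
    y = np.array([a[1] for a in TEMPORAL_ANCHORS])
    return np.linalg.solve(np.vander(t, 3, increasing=True), y)


_TEMPORAL_COEF = _temporal_coefficients()


def temporal_scaling_factor(t):
    """Temporal intensity scaling: the unique quadratic through the anchors
    0.1 at t=0 (onset, early C13), 1.0 at t=48 (around T5) and 0.7 at
    t=71.1 min (gastrulation)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0) or np.any(t > 71.1):
        raise ValueError("time outside [0, 71.1] min")
    c = _TEMPORAL_COEF
    out = c[0] + c[1] * t + c[2] * t * t
    return out if out.ndim else float(out)


def make_weights(yhat, epsilon: float = 0.1):
    """WLS weights from normalised intensity: v = 1/(epsilon + yhat)^2.

    Strictly decreasing in yhat, maximal (1/epsilon^2) where a gene is not
    expressed -- the ectopic-expression penalty.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    yhat = np.asarray(yhat, dtype=float)
    out = 1.0 / (epsilon + yhat) ** 2
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Expression dataset
# ---------------------------------------------------------------------------


class ExpressionDataset:
    """Target concentrations and WLS weights per (gene, time class, nucleus).

    Every (gene, time class) slice covers the full trunk lattice of its
    stage.  The canonical flat ordering -- used for cost evaluation and for
    the residual vector -- is time class (schedule order), then gene (spec
    order), then nucleus (anterior to posterior).
    """

    def __init__(self, spec: GeneNetworkSpec, values: dict, weights: dict,
                 lattices: dict, data_times: dict, provenance: str = ""):
        self.spec = spec
        self.time_classes = [tc for tc in data_times if tc in values]
        if set(values) != set(self.time_classes):
            raise ValueError("values keyed by unknown time classes")
        self._values = {}
        self._weights = {}
        self._lattices = {}
        for tc in self.time_classes:
            lat = lattices[tc]
            v = np.asarray(values[tc], dtype=float)
            w = np.asarray(weights[tc], dtype=float)
            want = (spec.n_genes, lat.n_nuclei)
            if v.shape != want or w.shape != want:
                raise ValueError(
                    f"slice {tc}: shapes {v.shape}/{w.shape}, expected {want}"
                )
            if np.any(v < 0):
                raise ValueError(f"negative concentrations in slice {tc}")
            if np.any(w <= 0):
                raise ValueError(f"non-positive weights in slice {tc}")
            self._values[tc] = v
            self._weights[tc] = w
            self._lattices[tc] = lat
        self.data_times = {tc: float(data_times[tc]) for tc in self.time_classes}
        self.provenance = provenance

    # -- structure -----------------------------------------------------------

    @property
    def n_points(self) -> int:
        return sum(v.size for v in self._values.values())

    def lattice_of(self, time_class: str) -> NucleusLattice:
        return self._lattices[time_class]

    def slice_matrix(self, time_class: str) -> np.ndarray:
        """(G, N) target concentrations for one time class."""
        return self._values[time_class]

    def weight_matrix(self, time_class: str) -> np.ndarray:
        return self._weights[time_class]

    @property
    def values(self) -> np.ndarray:
        """All target values, canonically ordered."""
        return np.concatenate([self._values[tc].ravel() for tc in self.time_classes])

    @property
    def weights(self) -> np.ndarray:
        return np.concatenate([self._weights[tc].ravel() for tc in self.time_classes])

    def with_weights(self, weights: dict) -> "ExpressionDataset":
        return ExpressionDataset(self.spec, self._values, weights,
                                 self._lattices, self.data_times, self.provenance)

    # -- I/O -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tc in self.time_classes:
            lat = self._lattices[tc]
            for gi, gene in enumerate(self.spec.gap_genes):
                for col, nuc in enumerate(lat.indices):
                    rows.append(
                        (gene, tc, self.data_times[tc], int(nuc),
                         lat.positions[col], self._values[tc][gi, col],
                         self._weights[tc][gi, col])
                    )
        return pd.DataFrame(
            rows, columns=["gene", "time_class", "time_min", "nucleus_index",
                           "ap_position", "value", "weight"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, spec: GeneNetworkSpec | None = None,
                 data_times: dict | None = None) -> "ExpressionDataset":
        """Read a dataset TSV.

        Files written by :meth:`to_tsv` are self-describing (time_min and
        ap_position columns recover the schedule and lattice geometry);
        legacy files without them fall back to the standard gap-gene
        schedule and stage lattices.
        """
        df = pd.read_csv(path, sep="\t")
        if spec is None:
            genes = list(dict.fromkeys(df.gene))
            if set(genes) == set(GeneNetworkSpec().gap_genes):
                genes = list(GeneNetworkSpec().gap_genes)
            ext = tuple(m for m in EXTERNAL_INPUTS if m not in genes)
            spec = GeneNetworkSpec(gap_genes=tuple(genes),
                                   external_inputs=ext,
                                   ap_range=(0.0, 100.0))
        if data_times is None:
            if "time_min" in df.columns:
                pairs = sorted(
                    {(tc, float(t))
                     for tc, t in zip(df.time_class, df.time_min)},
                    key=lambda p: p[1])
                data_times = dict(pairs)
            else:
                data_times = dict(DATA_TIMES)
        values, weights, lattices = {}, {}, {}
        for tc in [t for t in data_times if t in set(df.time_class)]:
            sub = df[df.time_class == tc]
            nuclei = np.sort(sub.nucleus_index.unique())
            if "ap_position" in sub.columns:
                row = sub.iloc[0]
                w = float(row.ap_position) / (float(row.nucleus_index) + 0.5)
                n_axis = round(100.0 / w)
                stage = {50: "C13", 100: "C14A"}.get(n_axis, "custom")
            else:
                stage = "C13" if tc == "C13" else "C14A"
                n_axis = {"C13": 50, "C14A": 100}[stage]
                w = 100.0 / n_axis
            lat = build_lattice(stage, (nuclei[0] * w, (nuclei[-1] + 1) * w - 1e-9),
                                n_axis=n_axis)
            v = np.zeros((spec.n_genes, lat.n_nuclei))
            wt = np.ones_like(v)
            for gi, gene in enumerate(spec.gap_genes):
                g = sub[sub.gene == gene].sort_values("nucleus_index")
                v[gi] = g.value.to_numpy()
                wt[gi] = g.weight.to_numpy()
            values[tc], weights[tc], lattices[tc] = v, wt, lat
        return cls(spec, values, weights, lattices, data_times)


def postprocess(profiles: dict, spec: GeneNetworkSpec,
                data_times: dict | None = None,
                ap_range=None, epsilon: float = 0.1,
                provenance: str = "") -> ExpressionDataset:
    """Apply the four post-processing steps and build the fitting dataset.

    ``profiles`` maps (gene, time_class) to a full-axis normalised profile
    already binned to the stage's axis bins (step 1).  Steps 2-4 -- spatial
    scaling, temporal scaling, x200 -- are applied in that order (the two
    scalings are independent multipliers and commute; binning must come
    first), then slices are restricted to the trunk lattice.  WLS weights are
    computed from the normalised pre-scaling intensities.
    """
    data_times = data_times or dict(DATA_TIMES)
    ap_range = ap_range or spec.ap_range
    time_classes = sorted(
        {tc for (_, tc) in profiles}, key=lambda tc: data_times[tc]
    )
    values, weights, lattices = {}, {}, {}
    for tc in time_classes:
        stage = "C13" if tc == "C13" else "C14A"
        lat = build_lattice(stage, ap_range)
        cols = lat.indices
        v = np.zeros((spec.n_genes, lat.n_nuclei))
        yhat = np.zeros_like(v)
        for gi, gene in enumerate(spec.gap_genes):
            prof = np.asarray(profiles[(gene, tc)], dtype=float)
            if prof.shape != (lat.n_axis,):
                raise ValueError(
                    f"profile {(gene, tc)} has {prof.shape[0]} bins, "
                    f"expected {lat.n_axis}"
                )
            yhat[gi] = prof[cols]
            v[gi] = (prof[cols]
                     * spatial_scaling_factor(lat.positions)
                     * temporal_scaling_factor(data_times[tc])
                     * 200.0)
        values[tc] = v
        weights[tc] = make_weights(yhat, epsilon)
        lattices[tc] = lat
    return ExpressionDataset(spec, values, weights, lattices, data_times,
                             provenance=provenance)


# ---------------------------------------------------------------------------
# Posterior Kr domain removal
# ---------------------------------------------------------------------------


def drop_posterior_kr(boundaries) -> list:
    """Remove the late posterior Kr domain from the fitting data.

    The posterior Kr domain arises in late C14A under terminal/Forkhead
    control and does not participate in segment determination; its boundary
    contributions are removed before profile assembly, so the corresponding
    nuclei are zero in the assembled dataset.  Idempotent; warns (no-op) if
    no posterior Kr boundaries are present.
    """
    out = [b for b in boundaries
           if not (b.gene == "Kr" and "posterior" in b.boundary_id)]
    if len(out) == len(boundaries):
        warnings.warn("no posterior Kr boundaries found; dataset unchanged",
                      stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Packaged fixture: the printed median mRNA boundary positions
# ---------------------------------------------------------------------------


def packaged_boundaries(default_boundary_width: float = 5.0) -> list:
    """Median boundary splines from the packaged mRNA boundary-position table.

    The table prints spline starting points x0; the end anchor is placed a
    default width into the domain (x2 = x0 + width for rising/anterior
    boundaries, x0 - width for falling/posterior ones).  Where a domain is
    narrower than two widths, the width is clipped so the rising and falling
    spans meet at the domain midpoint instead of overlapping.  Absent
    boundaries (dashes in the table) emit nothing: a domain without an
    anterior boundary extends in from the anterior end, one without a
    posterior boundary extends to the posterior end.
    """
    w = float(default_boundary_width)
    if w <= 0:
        raise ValueError("boundary width must be > 0")
    boundaries = []
    for tc, row in MRNA_BOUNDARY_TABLE.items():
        by_col = dict(zip(BOUNDARY_TABLE_COLUMNS, row))
        domains = []  # (gene, domain) in axis order
        for gene, domain, _ in BOUNDARY_TABLE_COLUMNS:
            if (gene, domain) not in domains:
                domains.append((gene, domain))
        for gene, domain in domains:
            xa = by_col.get((gene, domain, "A"))
            xp = by_col.get((gene, domain, "P"))
            width = w
            if xa is not None and xp is not None and xp - xa < 2.0 * w:
                width = max((xp - xa) / 2.0, 1e-6)
            if xa is not None:
                boundaries.append(BoundarySpline(
                    gene=gene, time_class=tc,
                    boundary_id=f"{gene}_{domain}_A", polarity=RISING,
                    x0=xa, y0=0.0, x2=min(xa + width, 100.0), y2=1.0,
                ))
            if xp is not None:
                boundaries.append(BoundarySpline(
                    gene=gene, time_class=tc,
                    boundary_id=f"{gene}_{domain}_P", polarity=FALLING,
                    x0=xp, y0=0.0, x2=max(xp - width, 0.0), y2=1.0,
                ))
    return boundaries


def load_boundary_table_fixture(default_boundary_width: float = 5.0,
                        ap_range=None, epsilon: float = 0.1,
                        spec: GeneNetworkSpec | None = None) -> ExpressionDataset:
    """The 9-time-class fitting dataset assembled from the packaged table."""
    spec = spec or GeneNetworkSpec()
    boundaries = packaged_boundaries(default_boundary_width)
    profiles = {}
    for tc in MRNA_BOUNDARY_TABLE:
        n_axis = 50 if tc == "C13" else 100
        for gene in spec.gap_genes:
            group = [b for b in boundaries
                     if b.gene == gene and b.time_class == tc]
            profiles[(gene, tc)] = assemble_profile(group, n_axis)
    return postprocess(profiles, spec, ap_range=ap_range, epsilon=epsilon,
                       provenance="packaged-boundary-fixture")


# ---------------------------------------------------------------------------
# Annotation TSV I/O
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = ["embryo_id", "gene", "time_class", "boundary_id",
                  "polarity", "x0", "y0", "x2", "y2"]


def boundaries_to_tsv(boundaries, path) -> None:
    df = pd.DataFrame(
        [(b.embryo_id, b.gene, b.time_class, b.boundary_id, b.polarity,
          b.x0, b.y0, b.x2, b.y2) for b in boundaries],
        columns=_ANNOT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def boundaries_from_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        BoundarySpline(
            gene=r.gene, time_class=r.time_class, boundary_id=r.boundary_id,
            polarity=r.polarity, x0=r.x0, y0=r.y0, x2=r.x2, y2=r.y2,
            embryo_id=str(r.embryo_id),
        )
        for r in df.itertuples()
    ]
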