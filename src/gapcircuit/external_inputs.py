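"""External regulator concentration profiles.

Gap gene circuits require concentration profiles for regulators that are not
themselves regulated by the trunk gap genes: the maternal gradients Bcd and
Cad and the terminal gap genes Tll and Hkb.  Profiles can come from measured
data or from artificial generators; both sides satisfy the same evaluation
contract -- a deterministic, non-negative function f(x % A-P, t min) -- and
the fitting machinery never branches on provenance.

Artificial generators:

* Bcd -- a time-independent anterior exponential gradient, fit by least
  squares to pooled samples across space and time.
* Cad -- a smooth posterior surface built from three qualitative features:
  complementarity to the Bcd gradient, increasing repression of the abdominal
  region (~50-80% A-P) over time, and a posterior stripe appearing around
  80% A-P from time class T6 onwards.
* Tll / Hkb -- time-invariant profiles from boundary positions averaged over
  all cleavage cycles and time classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .circuit_model import DATA_TIMES
from .dataprep import FALLING, RISING, BoundarySpline, profile_at

__all__ = [
    "InputProfile",
    "ExternalInputSet",
    "fit_bcd_exponential",
    "build_cad_profile",
    "time_invariant_profile",
    "default_artificial_inputs",
    "profiles_from_tsv",
    "profiles_to_tsv",
]

#: Default amplitude of artificial inputs on the x200 concentration scale.
DEFAULT_AMPLITUDE = 200.0


@dataclass(frozen=True)
class InputProfile:
    """A single external regulator profile: f(x, t) -> concentration."""

    name: str
    func: object  # callable (x array, t scalar) -> array
    provenance: str = "artificial"
    time_invariant: bool = False

    def __call__(self, x, t: float):
        out = np.asarray(self.func(np.asarray(x, dtype=float), float(t)),
                         dtype=float)
        return out

    def evaluate(self, x, t: float) -> np.ndarray:
        return np.maximum(self(x, t), 0.0)


class ExternalInputSet:
    """Ordered collection of external-input profiles for one circuit."""

    def __init__(self, profiles: dict):
        self.profiles = dict(profiles)
        self.names = tuple(self.profiles)

    def __getitem__(self, name: str) -> InputProfile:
        return self.profiles[name]

    @property
    def time_invariant(self) -> bool:
        return all(p.time_invariant for p in self.profiles.values())

    def evaluate_all(self, x, t: float) -> np.ndarray:
        """(M, len(x)) concentrations of all inputs at positions x, time t."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.stack([self.profiles[n].evaluate(x, t) for n in self.names])


# ---------------------------------------------------------------------------
# Bcd: time-independent exponential gradient
# ---------------------------------------------------------------------------


def fit_bcd_exponential(samples) -> InputProfile:
    """Fit A*exp(-x/L) to pooled (x, t, concentration) samples.

    The fit is by least squares in linear space (robust to near-zero
    posterior tails); the result is constant in time.
    """
    arr = np.asarray([(s[0], s[2]) for s in samples], dtype=float)
    if len(arr) < 3:
        raise ValueError("need at least 3 samples to fit the Bcd exponential")
    x, c = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 2:
        raise ValueError("degenerate x-spread: samples at a single position")

    def model(x, A, L):
        return A * np.exp(-x / L)

    A0 = max(float(c.max()), 1e-6)
    (A, L), _ = curve_fit(model, x, c, p0=(A0, 20.0), maxfev=20000)
    if A <= 0:
        raise ValueError(f"fitted amplitude A={A} is not positive")

    return InputProfile(
        name="bcd",
        func=lambda xx, tt, A=float(A), L=float(L): A * np.exp(-xx / L),
        provenance="artificial",
        time_invariant=True,
    )


def bcd_exponential(A: float = DEFAULT_AMPLITUDE, L: float = 20.0) -> InputProfile:
    """Artificial anterior Bcd gradient with given amplitude and length scale."""
    return InputProfile(
        name="bcd",
        func=lambda x, t, A=A, L=L: A * np.exp(-x / L),
        provenance="artificial",
        time_invariant=True,
    )


# ---------------------------------------------------------------------------
# Cad: feature-based posterior surface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CadFeatures:
    """Tunable features of the artificial Cad surface."""

    amplitude: float = DEFAULT_AMPLITUDE
    gradient_midpoint: float = 45.0   # % A-P where the posterior rise is centred
    gradient_scale: float = 8.0       # steepness of the rise
    abdominal_centre: float = 65.0    # centre of the repressed window (~50-80%)
    abdominal_width: float = 12.0
    abdominal_max_repression: float = 0.7  # fraction removed by t_end
    stripe_centre: float = 80.0
    stripe_width: float = 2.0
    stripe_amplitude_frac: float = 0.4     # relative to `amplitude`
    stripe_onset: float = DATA_TIMES["T6"]
    stripe_ramp: float = 6.0          # minutes to full stripe strength
    t_end: float = 71.1


def build_cad_profile(features: CadFeatures | None = None,
                      data_times: dict | None = None) -> InputProfile:
    """Smooth Cad surface satisfying the three qualitative features.

    (1) complementary to the anterior Bcd gradient (rising towards the
    posterior, plateau in the posterior region); (2) expression in the
    abdominal window decays over time; (3) a posterior stripe near the
    stripe centre appears at the onset time class and not before.
    """
    f = features or CadFeatures()
    data_times = data_times or dict(DATA_TIMES)
    if not any(np.isclose(f.stripe_onset, t) for t in data_times.values()):
        raise ValueError(
            f"stripe onset {f.stripe_onset} min is not one of the data times"
        )

    def func(x, t):
        base = f.amplitude / (1.0 + np.exp(-(x - f.gradient_midpoint)
                                           / f.gradient_scale))
        rho = f.abdominal_max_repression * min(max(t, 0.0), f.t_end) / f.t_end
        window = np.exp(-((x - f.abdominal_centre) / f.abdominal_width) ** 2)
        on = min(max((t - f.stripe_onset) / f.stripe_ramp + 1.0, 0.0), 1.0)
        stripe = (f.stripe_amplitude_frac * f.amplitude * on
                  * np.exp(-((x - f.stripe_centre) / f.stripe_width) ** 2))
        return base * (1.0 - rho * window) + stripe

    return InputProfile(name="cad", func=func, provenance="artificial",
                        time_invariant=False)


# ---------------------------------------------------------------------------
# Tll / Hkb: time-invariant averaged-boundary profiles
# ---------------------------------------------------------------------------


def time_invariant_profile(name: str, boundaries,
                           amplitude: float = DEFAULT_AMPLITUDE) -> InputProfile:
    """Time-invariant profile from boundaries averaged across time classes.

    ``boundaries`` is an iterable of :class:`BoundarySpline` observations of
    the same gene at different cleavage cycles / time classes.  Anchor
    positions are averaged (mean) per boundary id, the averaged boundaries
    are combined into a normalised domain profile, and the result is scaled
    by ``amplitude`` and constant in t.
    """
    boundaries = list(boundaries)
    if not boundaries:
        raise ValueError("time_invariant_profile requires at least one boundary")
    by_id: dict[str, list] = {}
    for b in boundaries:
        by_id.setdefault(b.boundary_id, []).append(b)
    averaged = []
    for bid, group in by_id.items():
        first = group[0]
        averaged.append(BoundarySpline(
            gene=first.gene, time_class="all", boundary_id=bid,
            polarity=first.polarity,
            x0=float(np.mean([b.x0 for b in group])),
            y0=float(np.mean([b.y0 for b in group])),
            x2=float(np.mean([b.x2 for b in group])),
            y2=float(np.mean([b.y2 for b in group])),
        ))

    def func(x, t, bs=tuple(averaged), amp=float(amplitude)):
        return amp * profile_at(bs, x)

    return InputProfile(name=name, func=func, provenance="artificial",
                        time_invariant=True)


#: Default terminal-gene boundary tables (posterior tll domain and hkb pole
#: domain), used when no measured boundaries are supplied.
_DEFAULT_TLL = (
    BoundarySpline("tll", "all", "tll_posterior_A", RISING, 72.0, 0.0, 78.0, 1.0),
    BoundarySpline("tll", "all", "tll_posterior_P", FALLING, 95.0, 0.0, 89.0, 1.0),
)
_DEFAULT_HKB = (
    BoundarySpline("hkb", "all", "hkb_posterior_A", RISING, 88.0, 0.0, 93.0, 1.0),
)


def default_artificial_inputs(bcd_A: float = DEFAULT_AMPLITUDE,
                              bcd_L: float = 20.0,
                              cad: CadFeatures | None = None,
                              amplitude: float = DEFAULT_AMPLITUDE
                              ) -> ExternalInputSet:
    """The fully artificial external-input set (Bcd, Cad, Tll, Hkb)."""
    return ExternalInputSet({
        "bcd": bcd_exponential(bcd_A, bcd_L),
        "cad": build_cad_profile(cad),
        "tll": time_invariant_profile("tll", _DEFAULT_TLL, amplitude),
        "hkb": time_invariant_profile("hkb", _DEFAULT_HKB, amplitude),
    })


# ---------------------------------------------------------------------------
# Measured profiles: tabulated TSV -> interpolating profile
# ---------------------------------------------------------------------------


def profiles_from_tsv(path, positions=None) -> ExternalInputSet:
    """Measured input profiles from a TSV with columns
    (input_gene, time_min, nucleus_index, concentration).

    Nucleus indices refer to the 100-bin C14A axis (index i centred at
    i + 0.5 % A-P) unless ``positions`` maps indices to % A-P directly.
    Evaluation interpolates linearly in space and time and clamps outside
    the tabulated range.
    """
    df = pd.read_csv(path, sep="\t")
    profiles = {}
    for name, sub in df.groupby("input_gene"):
        times = np.sort(sub.time_min.unique())
        grids = []
        for t in times:
            s = sub[sub.time_min == t].sort_values("nucleus_index")
            x = (s.nucleus_index.to_numpy() + 0.5) if positions is None \
                else np.asarray([positions[i] for i in s.nucleus_index])
            grids.append((np.asarray(x, dtype=float),
                          s.concentration.to_numpy(dtype=float)))

        def func(x, t, times=times, grids=grids):
            x = np.asarray(x, dtype=float)
            t = min(max(t, times[0]), times[-1])
            k = int(np.searchsorted(times, t, side="right") - 1)
            k = min(k, len(times) - 2) if len(times) > 1 else 0
            xa, ca = grids[k]
            va = np.interp(x, xa, ca)
            if len(times) == 1 or times[k + 1] == times[k]:
                return va
            xb, cb = grids[k + 1]
            vb = np.interp(x, xb, cb)
            frac = (t - times[k]) / (times[k + 1] - times[k])
            return va + frac * (vb - va)

        profiles[name] = InputProfile(
            name=name, func=func, provenance="measured",
            time_invariant=len(times) == 1,
        )
    return ExternalInputSet(profiles)


def profiles_to_tsv(inputs: ExternalInputSet, path, times, n_axis: int = 100
                    ) -> None:
    """Tabulate an input set at nucleus centres of an ``n_axis``-bin lattice."""
    x = (np.arange(n_axis) + 0.5) * (100.0 / n_axis)
    rows = []
    for name in inputs.names:
        for t in times:
            conc = inputs[name].evaluate(x, t)
            for i, c in enumerate(conc):
                rows.append((name, float(t), i, float(c)))
    pd.DataFrame(rows, columns=["input_gene", "time_min", "nucleus_index",
                                "concentration"]).to_csv(path, sep="\t",
                                                         index=False)
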