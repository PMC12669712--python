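"""Mass-photometry peak fitting and complex detection.

Converts single-molecule landing-event contrasts to molecular masses via a
linear calibration (mass = a * contrast + b), fits a Gaussian mixture to the
raw mass values by expectation-maximization with the component count chosen
by BIC, and decides whether a mixed sample contains a higher-mass species
(a bound complex) absent from the individual samples.

The mixture is fit on raw masses, not on histogram bins; a histogram at a
configurable bin width is attached to the fitted peak set for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture


@dataclass
class MassEventSet:
    """Landing events in mass (kDa) or contrast units.

    When ``units == "contrast"`` a calibration (slope a in kDa per contrast
    unit, intercept b in kDa) is required to recover masses.
    """

    values: np.ndarray
    units: str = "mass"
    calibration: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("need at least one event")
        if self.units not in ("mass", "contrast"):
            raise ValueError("units must be 'mass' or 'contrast'")
        if self.units == "contrast":
            if self.calibration is None:
                raise ValueError("contrast units require a calibration (a, b)")
            if self.calibration[0] == 0:
                raise ValueError("calibration slope must be nonzero")

    def masses(self) -> np.ndarray:
        if self.units == "mass":
            return self.values
        a, b = self.calibration
        return a * self.values + b


@dataclass
class Peak:
    """One Gaussian component: center mu (kDa), width sigma (kDa), weight w."""

    center: float
    width: float
    weight: float


@dataclass
class PeakSet:
    """Fitted Gaussian peaks, centers sorted ascending, weights summing to 1."""

    peaks: list[Peak]
    degenerate: bool = False
    histogram: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.center)
        if not self.degenerate:
            total = sum(p.weight for p in self.peaks)
            if not np.isclose(total, 1.0):
                raise ValueError("peak weights must sum to 1")
            if any(p.width <= 0 or p.weight <= 0 for p in self.peaks):
                raise ValueError("peak widths and weights must be positive")

    @property
    def k(self) -> int:
        return len(self.peaks)

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.peaks])

    def top_peak(self) -> Peak:
        """The dominant (highest-weight) peak."""
        return max(self.peaks, key=lambda p: p.weight)


@dataclass
class ComplexCall:
    """Decision on complex formation in a mixed sample.

    Positive when the mixture has a sufficiently abundant peak above every
    individual-sample peak by more than ``mass_tol``; ``sum_consistent``
    reports whether that peak sits within ``mass_tol`` of the sum of the
    dominant A and B peak centers.
    """

    is_complex: bool
    complex_peak: Peak | None
    sum_consistent: bool | None
    mass_tol: float


def fit_mass_peaks(
    events: MassEventSet,
    k_max: int = 4,
    bin_width: float = 5.0,
    seed: int = 0,
) -> PeakSet:
    """Fit 1..k_max Gaussian components to the event masses; select k by BIC.

    EM initialization is k-means based with a fixed random state, so the fit
    is deterministic given the seed.  Fewer than 50 events with k_max >= 2
    is an error; all-identical masses yield a single zero-width peak flagged
    degenerate.
    """
    masses = events.masses()
    if masses.size < 50 and k_max >= 2:
        raise ValueError(
            f"need >= 50 events to fit up to {k_max} components; got {masses.size}"
        )
    if np.ptp(masses) == 0:
        return PeakSet(
            peaks=[Peak(center=float(masses[0]), width=0.0, weight=1.0)],
            degenerate=True,
        )
    x = masses.reshape(-1, 1)
    best = None
    best_bic = np.inf
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=3,
            random_state=int(seed) % (2**31),
            reg_covar=1e-6,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best = gm
    peaks = [
        Peak(
            center=float(best.means_[i, 0]),
            width=float(np.sqrt(best.covariances_[i, 0, 0])),
            weight=float(best.weights_[i]),
        )
        for i in range(best.n_components)
    ]
    lo = np.floor(masses.min() / bin_width) * bin_width
    hi = np.ceil(masses.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(masses, bins=edges)
    return PeakSet(peaks=peaks, histogram=(counts, edges))


def detect_complex(
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    peaks_mix: PeakSet,
    mass_tol: float | None = None,
    weight_min: float = 0.1,
) -> ComplexCall:
    """Decide whether the mixed sample shows a higher-mass complex.

    Positive iff the mixture has a peak with weight >= ``weight_min`` whose
    center exceeds every peak center of A and of B by more than
    ``mass_tol``.  ``mass_tol`` defaults to twice the pooled width of the
    dominant A and B peaks, sqrt(sigma_A^2 + sigma_B^2).  The call also
    reports whether the complex center is within ``mass_tol`` of the sum of
    the dominant A and B centers (1:1 stoichiometry check).
    """
    top_a, top_b = peaks_a.top_peak(), peaks_b.top_peak()
    if mass_tol is None:
        mass_tol = 2.0 * float(np.hypot(top_a.width, top_b.width))
    ceiling = max(peaks_a.centers.max(), peaks_b.centers.max())
    candidates = [
        p for p in peaks_mix.peaks
        if p.weight >= weight_min and p.center > ceiling + mass_tol
    ]
    if not candidates:
        return ComplexCall(
            is_complex=False, complex_peak=None, sum_consistent=None,
            mass_tol=mass_tol,
        )
    peak = max(candidates, key=lambda p: p.weight)
    expected = top_a.center + top_b.center
    return ComplexCall(
        is_complex=True,
        complex_peak=peak,
        sum_consistent=bool(abs(peak.center - expected) <= mass_tol),
        mass_tol=mass_tol,
    )
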