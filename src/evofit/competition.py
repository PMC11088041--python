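"""Selection coefficients from two-competitor assays.

The central statistic is the selection coefficient of a test strain
competed against a labelled (GFP-tagged) reference::

    S = ln(test_f / ref_f) - ln(test_i / ref_i)

i.e. the change in the natural-log odds of the test competitor between the
start and end of one competition episode.  ``S > 0`` means the test strain
gained on the reference.  Raw coefficients are normalised by subtracting
the mean S of parental-vs-reference control competitions, which pins the
parent at S = 0 and cancels the fitness cost of the fluorescent tag.

For propagation assays S is additionally scaled per cell doubling
(``S/d``), with doublings estimated as the log2 fold change in cell
density corrected for the transfer dilution.  Serial-transfer competitions
accumulate S and doublings passage by passage (the end of passage 1 is the
measurement baseline) and the per-doubling fitness is the OLS slope of
cumulative S on cumulative doublings, corrected by subtracting the slope
of the matching reference competition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CompetitionObservation",
    "DoublingRecord",
    "SelectionResult",
    "SerialTransferSeries",
    "CumulativeFitnessTrack",
    "FitnessEstimate",
    "SurvivalAssay",
    "ZeroCompetitorError",
    "selection_coefficient",
    "normalize_selection",
    "estimate_doublings",
    "selection_per_doubling",
    "cumulative_fitness",
    "fit_s_per_doubling",
    "shock_survival",
    "expected_ethanol_titer",
    "ETHANOL_YIELD_G_PER_G",
    "ETHANOL_DENSITY_G_PER_ML",
]

#: Theoretical ethanol yield from reducing sugars (glucose/fructose), g/g.
ETHANOL_YIELD_G_PER_G = 0.511

#: Density of ethanol at 20 degC, g/mL; 1% v/v = 10 mL/L = 7.89 g/L.
ETHANOL_DENSITY_G_PER_ML = 0.789

#: Default flow-cytometry acquisition size used to convert proportions to
#: pseudo-counts when a table stores fractions instead of event counts.
DEFAULT_EVENTS = 10_000


class ZeroCompetitorError(ValueError):
    """A competitor had zero events at a timepoint, so the log-odds is undefined."""


@dataclass(frozen=True)
class CompetitionObservation:
    """Event counts for one competition episode (start and end).

    ``test_*`` are the unlabelled test-strain events, ``ref_*`` the
    GFP-labelled reference events.  Values may be given as proportions in
    [0, 1]; use :meth:`from_proportions` to convert with a stated total.
    """

    test_initial: float
    ref_initial: float
    test_final: float
    ref_final: float
    condition: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        for name in ("test_initial", "ref_initial", "test_final", "ref_final"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative count, got {v!r}")
        if self.test_initial + self.ref_initial <= 0:
            raise ValueError("initial timepoint has no events")
        if self.test_final + self.ref_final <= 0:
            raise ValueError("final timepoint has no events")

    @classmethod
    def from_proportions(
        cls,
        test_initial: float,
        ref_initial: float,
        test_final: float,
        ref_final: float,
        *,
        events: float = DEFAULT_EVENTS,
        **kwargs,
    ) -> "CompetitionObservation":
        """Build an observation from per-timepoint proportions.

        Proportions are scaled by ``events`` (default 10,000, a standard
        fixed-event cytometry acquisition).  S is invariant to this scale;
        it only matters if counts are inspected directly.
        """
        for p, q, when in ((test_initial, ref_initial, "initial"), (test_final, ref_final, "final")):
            if not (0 <= p <= 1 and 0 <= q <= 1):
                raise ValueError(f"{when} proportions must lie in [0, 1]")
            if not math.isclose(p + q, 1.0, abs_tol=1e-6):
                raise ValueError(f"{when} proportions must sum to 1, got {p + q}")
        return cls(
            test_initial=test_initial * events,
            ref_initial=ref_initial * events,
            test_final=test_final * events,
            ref_final=ref_final * events,
            **kwargs,
        )

    def swapped(self) -> "CompetitionObservation":
        """The same episode with test/reference labels exchanged."""
        return CompetitionObservation(
            test_initial=self.ref_initial,
            ref_initial=self.test_initial,
            test_final=self.ref_final,
            ref_final=self.test_final,
            condition=self.condition,
            replicate_id=self.replicate_id,
        )


@dataclass(frozen=True)
class DoublingRecord:
    """Cell densities and transfer volumes for one propagation.

    ``density_initial`` is the density of the source mixture; the
    effective in-culture starting density is
    ``density_initial * inoculum_volume / culture_volume``.
    """

    density_initial: float
    density_final: float
    inoculum_volume: float = 1.0
    culture_volume: float = 1.0

    def __post_init__(self) -> None:
        if self.density_initial <= 0 or self.density_final <= 0:
            raise ValueError("densities must be strictly positive")
        if self.inoculum_volume <= 0 or self.culture_volume <= 0:
            raise ValueError("volumes must be strictly positive")
        if self.inoculum_volume > self.culture_volume:
            raise ValueError("inoculum_volume cannot exceed culture_volume")


@dataclass(frozen=True)
class SelectionResult:
    """A selection coefficient with its reference normalisation."""

    s_raw: float
    s_normalized: float
    reference_mean: float
    doublings: float | None = None
    s_per_doubling: float | None = None
    #: normalized value for each reference replicate (for dispersion estimates)
    reference_normalized: tuple[float, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class SerialTransferSeries:
    """Ordered passages of one strain's serial-transfer competition."""

    passages: tuple[tuple[CompetitionObservation, DoublingRecord], ...]
    strain_label: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.passages) < 2:
            raise ValueError("a serial-transfer series needs at least 2 passages")

    def __len__(self) -> int:
        return len(self.passages)


@dataclass(frozen=True)
class CumulativeFitnessTrack:
    """Per-passage cumulative S and doublings, anchored at (0, 0).

    The baseline is the end of passage 1: entry ``p`` holds sums over
    passages 2..p, so a 5-passage series yields 5 entries starting (0, 0).
    """

    cumulative_s: tuple[float, ...]
    cumulative_doublings: tuple[float, ...]
    strain_label: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.cumulative_s) != len(self.cumulative_doublings):
            raise ValueError("track arrays must have equal length")
        if not self.cumulative_s or self.cumulative_s[0] != 0 or self.cumulative_doublings[0] != 0:
            raise ValueError("track must start at (0, 0)")
        if any(b < a - 1e-12 for a, b in zip(self.cumulative_doublings, self.cumulative_doublings[1:])):
            raise ValueError("cumulative doublings must be non-decreasing")


@dataclass(frozen=True)
class FitnessEstimate:
    """OLS per-doubling fitness with reference-slope correction."""

    slope_raw: float
    intercept: float
    r_squared: float
    reference_slope: float
    slope_corrected: float
    n_points: int


@dataclass(frozen=True)
class SurvivalAssay:
    """CFU plate counts for a shock-survival measurement."""

    cfu_treated: float
    cfu_control: float
    dilution_treated: float = 1e-5
    dilution_control: float = 1e-5
    plated_volume: float = 1.0

    def __post_init__(self) -> None:
        if self.cfu_treated < 0 or self.cfu_control < 0:
            raise ValueError("CFU counts must be non-negative")
        for name in ("dilution_treated", "dilution_control"):
            d = getattr(self, name)
            if not (0 < d <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.plated_volume <= 0:
            raise ValueError("plated_volume must be positive")


def selection_coefficient(obs: CompetitionObservation, *, pseudocount: bool = False) -> float:
    """Selection coefficient S of the test strain over one episode.

    ``S = ln(test_final/ref_final) - ln(test_initial/ref_initial)``

    Parameters
    ----------
    obs
        Event counts at the two timepoints.
    pseudocount
        Add 0.5 to all four counts (Haldane correction) instead of
        raising on a zero count.  Off by default: a silent pseudocount
        biases S when counts are small.
    """
    counts = {
        "test_initial": obs.test_initial,
        "ref_initial": obs.ref_initial,
        "test_final": obs.test_final,
        "ref_final": obs.ref_final,
    }
    if pseudocount:
        counts = {k: v + 0.5 for k, v in counts.items()}
    for name, v in counts.items():
        if v <= 0:
            raise ZeroCompetitorError(
                f"zero-competitor count in field '{name}'; "
                "S is undefined (pass pseudocount=True to apply +0.5 to all counts)"
            )
    return math.log(counts["test_final"] / counts["ref_final"]) - math.log(
        counts["test_initial"] / counts["ref_initial"]
    )


def normalize_selection(
    s_test: float, s_reference_replicates: Sequence[float]
) -> SelectionResult:
    """Normalise a raw S by subtracting the mean of reference competitions.

    The reference competitions (parent vs. tagged tester) define S = 0, so
    the normalised value expresses fitness relative to the parent and
    discounts the cost of the fluorescent tag.
    """
    refs = list(s_reference_replicates)
    if not refs:
        raise ValueError("at least one reference replicate is required")
    ref_mean = float(np.mean(refs))
    return SelectionResult(
        s_raw=float(s_test),
        s_normalized=float(s_test) - ref_mean,
        reference_mean=ref_mean,
        reference_normalized=tuple(r - ref_mean for r in refs),
    )


def estimate_doublings(rec: DoublingRecord) -> float:
    """Cell doublings during one propagation.

    ``d = log2(density_final / (density_initial * inoculum/culture))``.
    May be negative if the population declined.
    """
    effective_initial = rec.density_initial * (rec.inoculum_volume / rec.culture_volume)
    return math.log2(rec.density_final / effective_initial)


def selection_per_doubling(s: float, d: float) -> float:
    """Scale a selection coefficient per cell doubling (S/d)."""
    if d == 0:
        raise ValueError("no doublings; per-doubling fitness undefined")
    return s / d


def cumulative_fitness(series: SerialTransferSeries) -> CumulativeFitnessTrack:
    """Cumulative S and doublings across serial transfers.

    The competitor proportions at the end of passage 1 are the measurement
    baseline, so the track starts at (0, 0) and accumulates the per-passage
    S and doublings of passages 2..p.
    """
    cum_s = [0.0]
    cum_d = [0.0]
    for idx, (obs, rec) in enumerate(series.passages[1:], start=2):
        try:
            s = selection_coefficient(obs)
        except ZeroCompetitorError as err:
            raise ZeroCompetitorError(f"passage {idx}: {err}") from err
        cum_s.append(cum_s[-1] + s)
        cum_d.append(cum_d[-1] + estimate_doublings(rec))
    return CumulativeFitnessTrack(
        cumulative_s=tuple(cum_s),
        cumulative_doublings=tuple(cum_d),
        strain_label=series.strain_label,
        condition=series.condition,
    )


def _ols(x: np.ndarray, y: np.ndarray, through_origin: bool) -> tuple[float, float, float]:
    """Return (slope, intercept, r_squared) for y ~ x."""
    if through_origin:
        sxx = float(x @ x)
        slope = float(x @ y) / sxx
        resid = y - slope * x
        tss = float(y @ y)  # uncentred TSS for a no-intercept model
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
        return slope, 0.0, r2
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue) ** 2


def fit_s_per_doubling(
    track: CumulativeFitnessTrack,
    reference_track: CumulativeFitnessTrack,
    *,
    through_origin: bool = False,
    per_passage_correction: bool = False,
) -> FitnessEstimate:
    """Per-doubling fitness from a cumulative track, reference-corrected.

    Both tracks are fitted by OLS of cumulative S on cumulative doublings
    (free intercept by default, matching a spreadsheet trendline; set
    ``through_origin=True`` to force the fit through the (0, 0) anchor).
    The corrected slope subtracts the reference competition's slope, which
    removes shared drift such as the tag's expression cost.

    With ``per_passage_correction=True`` the reference slope times the
    test track's cumulative doublings is subtracted from the test
    cumulative S point by point before fitting; when the two doubling
    schedules match this equals the slope-level subtraction.
    """
    for name, t in (("track", track), ("reference_track", reference_track)):
        if len(set(t.cumulative_doublings)) < 2:
            raise ValueError(f"degenerate regression: {name} has no spread in cumulative doublings")
        if len(t.cumulative_s) < 2:
            raise ValueError(f"{name} needs at least 2 points")

    x = np.asarray(track.cumulative_doublings, dtype=float)
    y = np.asarray(track.cumulative_s, dtype=float)
    xr = np.asarray(reference_track.cumulative_doublings, dtype=float)
    yr = np.asarray(reference_track.cumulative_s, dtype=float)

    ref_slope, _, _ = _ols(xr, yr, through_origin)
    slope_raw, intercept, r2 = _ols(x, y, through_origin)
    if per_passage_correction:
        slope_corrected, _, _ = _ols(x, y - ref_slope * x, through_origin)
    else:
        slope_corrected = slope_raw - ref_slope
    return FitnessEstimate(
        slope_raw=slope_raw,
        intercept=intercept,
        r_squared=r2,
        reference_slope=ref_slope,
        slope_corrected=slope_corrected,
        n_points=len(x),
    )


def shock_survival(assay: SurvivalAssay) -> float:
    """Percent survival from CFU counts, control plate = 100%.

    Counts are scaled to pre-dilution concentrations before forming the
    ratio, so treated and control plates may use different dilutions.
    """
    if assay.cfu_control == 0:
        raise ValueError("control plate has zero CFU; survival undefined")
    treated = assay.cfu_treated / assay.dilution_treated / assay.plated_volume
    control = assay.cfu_control / assay.dilution_control / assay.plated_volume
    return 100.0 * treated / control


def expected_ethanol_titer(
    trs_g_per_l: float,
    efficiency: float = 0.90,
    *,
    ethanol_density: float = ETHANOL_DENSITY_G_PER_ML,
) -> tuple[float, float]:
    """Expected ethanol titer from total reducing sugars.

    Returns ``(g ethanol per L, % v/v)`` using the theoretical yield of
    0.511 g ethanol per g of glucose/fructose, scaled by the conversion
    ``efficiency`` (industrial fermentations reach ~90% of theoretical).
    The v/v conversion divides by ``ethanol_density * 10`` g/L per % v/v.
    """
    if trs_g_per_l < 0:
        raise ValueError("TRS must be non-negative")
    if not (0 < efficiency <= 1):
        raise ValueError("efficiency must lie in (0, 1]")
    grams = efficiency * ETHANOL_YIELD_G_PER_G * trs_g_per_l
    pct_vv = grams / (ethanol_density * 10.0)
    return grams, pct_vv
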