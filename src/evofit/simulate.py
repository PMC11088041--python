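"""Synthetic raw data with the statistical structure the pipeline assumes.

Every generator is a pure, seeded function of its parameters and yields
objects that satisfy the invariants of the consuming modules, so each
analysis stage can be tested against known ground truth at desk scale.

Competition series model
------------------------
Fitness is parameterised per doubling on the log2-odds scale: over ``d``
doublings the true odds of the test competitor are multiplied by
``2**(s_per_doubling * d)``.  Because the selection coefficient is
defined on the natural-log scale, a single passage of ``d`` doublings has
expected ``S = s_per_doubling * d * ln(2)`` — divide an ln-scale slope by
``ln 2`` to recover the per-doubling input.  Each measurement draws
labelled/unlabelled counts binomially from the true fraction (binomial
sampling is the only noise source; no gating misclassification by
default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .competition import (
    CompetitionObservation,
    DoublingRecord,
    SerialTransferSeries,
    SurvivalAssay,
)
from .growth import GrowthCurve
from .variants import VariantRecord

__all__ = [
    "CompetitionSimParams",
    "GrowthSimParams",
    "VariantSimParams",
    "simulate_competition",
    "simulate_growth_curve",
    "simulate_variant_tables",
    "simulate_survival_assay",
    "LN2",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class CompetitionSimParams:
    """Ground truth for a serial-transfer competition simulation.

    Defaults mirror the study regime emulated: 1:1 starting mixture,
    10,000 cytometry events per measurement, 5 passages of ~6 doublings
    (propagation in ethanol-supplemented rich medium runs ~5-7 doublings
    per passage; ethanol-free medium ~8-10).
    """

    s_per_doubling: float = 0.0
    doublings_per_passage: float = 6.0
    n_passages: int = 5
    initial_test_fraction: float = 0.5
    events_per_measurement: int = 10_000
    seed: int = 0
    misclassification_rate: float = 0.0
    #: density of the stationary mixture sampled for each transfer, cells/mL
    transfer_density: float = 1.0e8
    inoculum_volume_ml: float = 0.02
    culture_volume_ml: float = 20.0

    def __post_init__(self) -> None:
        if self.events_per_measurement <= 0:
            raise ValueError("events_per_measurement must be > 0")
        if self.n_passages < 1:
            raise ValueError("n_passages must be >= 1")
        if not (0 < self.initial_test_fraction < 1):
            raise ValueError("initial_test_fraction must lie in (0, 1)")
        if not (0 <= self.misclassification_rate < 0.5):
            raise ValueError("misclassification_rate must lie in [0, 0.5)")


@dataclass(frozen=True)
class GrowthSimParams:
    """Growth-curve simulation parameters (µ in 1/h, times in h).

    The trajectory is a generalised logistic that is exponential at rate
    ``mu`` until shortly before the plateau at ``capacity``;
    ``saturation_sharpness`` controls how abruptly growth saturates
    (1 = the textbook logistic, whose deceleration already distorts the
    measured mid-OD window; the default 6 emulates plate-reader curves
    that stay log-linear through the fitting window).
    """

    mu: float = 0.35
    od0: float = 0.05
    capacity: float = 1.8
    lag: float = 0.0
    noise_sd: float = 0.01
    sample_interval: float = 0.25
    duration: float = 24.0
    seed: int = 0
    saturation_sharpness: float = 6.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if not (self.capacity > self.od0 > 0):
            raise ValueError("need capacity > od0 > 0")
        if self.noise_sd < 0 or self.lag < 0:
            raise ValueError("noise_sd and lag must be non-negative")
        if self.sample_interval <= 0 or self.duration <= 0:
            raise ValueError("sample_interval and duration must be > 0")
        if self.saturation_sharpness < 1:
            raise ValueError("saturation_sharpness must be >= 1")


@dataclass(frozen=True)
class VariantSimParams:
    """Parent/child variant-table simulation parameters.

    The child clone carries every parental polymorphism plus ``n_de_novo``
    planted variants at disjoint coordinates, emulating an evolved clone
    in a recombinant background.  De novo frequencies default to a point
    mass at 1.0 (haploid single-colony isolates).
    """

    n_contigs: int = 3
    contig_lengths: tuple[int, ...] = (200_000, 150_000, 100_000)
    n_parental_polymorphisms: int = 500
    n_de_novo: int = 12
    de_novo_frequencies: tuple[float, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or len(self.contig_lengths) != self.n_contigs:
            raise ValueError("contig_lengths must list one length per contig")
        if self.n_parental_polymorphisms < 0 or self.n_de_novo < 0:
            raise ValueError("variant counts must be non-negative")
        if self.de_novo_frequencies and len(self.de_novo_frequencies) != self.n_de_novo:
            raise ValueError("de_novo_frequencies must have one entry per de novo variant")


def simulate_competition(
    params: CompetitionSimParams,
) -> tuple[SerialTransferSeries, dict]:
    """Simulate a serial-transfer competition with recorded ground truth.

    Per passage the true test fraction evolves deterministically on the
    log2-odds scale; start/end counts are binomial draws from the true
    fractions with ``events_per_measurement`` trials.  Densities and
    transfer volumes are consistent with ``doublings_per_passage`` so the
    doubling estimator recovers the schedule exactly.

    Returns the series and a ground-truth dict with the true per-passage
    fractions, per-passage expected S, and the ln-scale slope
    ``s_per_doubling * ln 2`` that an ideal estimator would measure.
    """
    rng = np.random.default_rng(params.seed)
    d = params.doublings_per_passage
    n_events = params.events_per_measurement
    odds_factor = 2.0 ** (params.s_per_doubling * d)

    # density schedule: stationary mixture diluted into fresh medium, then d doublings
    dilution = params.inoculum_volume_ml / params.culture_volume_ml
    density_final = params.transfer_density * dilution * 2.0**d

    def measure(true_fraction: float) -> int:
        p = true_fraction
        m = params.misclassification_rate
        if m:
            p = p * (1 - m) + (1 - p) * m
        return int(rng.binomial(n_events, p))

    passages = []
    fraction = params.initial_test_fraction
    true_fractions = []
    for _ in range(params.n_passages):
        start_fraction = fraction
        odds_end = (start_fraction / (1 - start_fraction)) * odds_factor
        end_fraction = odds_end / (1 + odds_end)

        test_i = measure(start_fraction)
        test_f = measure(end_fraction)
        # guard against an all-one-competitor draw at extreme fractions
        test_i = min(max(test_i, 1), n_events - 1)
        test_f = min(max(test_f, 1), n_events - 1)
        obs = CompetitionObservation(
            test_initial=test_i,
            ref_initial=n_events - test_i,
            test_final=test_f,
            ref_final=n_events - test_f,
        )
        rec = DoublingRecord(
            density_initial=params.transfer_density,
            density_final=density_final,
            inoculum_volume=params.inoculum_volume_ml,
            culture_volume=params.culture_volume_ml,
        )
        passages.append((obs, rec))
        true_fractions.append((start_fraction, end_fraction))
        fraction = end_fraction  # the transfer preserves proportions

    series = SerialTransferSeries(passages=tuple(passages))
    truth = {
        "s_per_doubling": params.s_per_doubling,
        "doublings_per_passage": d,
        "expected_s_per_passage": params.s_per_doubling * d * LN2,
        "ln_slope": params.s_per_doubling * LN2,
        "true_fractions": true_fractions,
    }
    return series, truth


def simulate_growth_curve(
    params: GrowthSimParams,
    *,
    strain_label: str = "sim",
    condition: str = "",
    replicate_id: str = "",
) -> GrowthCurve:
    """Simulate a saturating OD600 time series with multiplicative noise.

    ``OD(t) = K * x / (1 + x**p)**(1/p)`` with
    ``x = x0 * exp(mu * (t - lag))``, ``x0 = od0 / (K**p - od0**p)**(1/p)``
    (so OD(0) = od0 exactly; x is held at x0 before the lag ends) and
    ``p = saturation_sharpness``.  For ``p = 1`` this is exactly the
    textbook logistic ``K / (1 + ((K - od0)/od0) * exp(-mu*(t - lag)))``;
    larger ``p`` keeps the curve exponential until closer to the plateau.
    Noise multiplies each point by ``1 + N(0, noise_sd)``; values are
    clipped strictly positive.
    """
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration + 1e-9, params.sample_interval)
    K, od0, p = params.capacity, params.od0, params.saturation_sharpness
    shifted = np.maximum(t - params.lag, 0.0)
    x0 = od0 / (K**p - od0**p) ** (1.0 / p)
    x = x0 * np.exp(params.mu * shifted)
    od = K * x / (1.0 + x**p) ** (1.0 / p)
    if params.noise_sd > 0:
        od = od * (1.0 + rng.normal(0.0, params.noise_sd, size=od.shape))
    od = np.clip(od, 1e-6, None)
    return GrowthCurve(
        times=tuple(t.tolist()),
        od600=tuple(od.tolist()),
        strain_label=strain_label,
        condition=condition,
        replicate_id=replicate_id,
    )


_BASES = ("A", "C", "G", "T")

_GENE_POOL_SIZE = 120


def _random_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def simulate_variant_tables(
    params: VariantSimParams,
) -> tuple[list[VariantRecord], list[VariantRecord], list[VariantRecord]]:
    """Simulate (parental catalogue, child variants, planted de novo truth).

    The child list is the union of the parental catalogue and the planted
    de novo set at disjoint (contig, position) keys, so subtracting the
    parental catalogue from the child must recover exactly the planted
    set.  About one variant in six is an indel; indels are emitted in a
    deliberately padded (non-minimal) spelling so representation
    normalisation is exercised downstream.
    """
    rng = np.random.default_rng(params.seed)
    total = params.n_parental_polymorphisms + params.n_de_novo
    contigs = [f"chr{'I' * (i + 1)}" for i in range(params.n_contigs)]

    weights = np.asarray(params.contig_lengths, dtype=float)
    weights = weights / weights.sum()
    counts = rng.multinomial(total, weights)
    if any(c > length for c, length in zip(counts, params.contig_lengths)):
        raise ValueError("requested variant counts exceed available positions")

    sites: list[tuple[str, int]] = []
    for contig, length, count in zip(contigs, params.contig_lengths, counts):
        # positions leave headroom for padded indel spellings
        positions = rng.choice(np.arange(10, length - 10), size=count, replace=False)
        sites.extend((contig, int(p)) for p in sorted(positions))
    rng.shuffle(sites)  # type: ignore[arg-type]

    def make_record(site: tuple[str, int], frequency: float, clone_id: str) -> VariantRecord:
        chrom, pos = site
        gene = f"GENE{int(rng.integers(_GENE_POOL_SIZE)):04d}"
        roll = rng.random()
        if roll < 1 / 6:  # padded indel spelling, e.g. ref=AT alt=ATT at pos-1
            anchor = _BASES[rng.integers(4)]
            inserted = _BASES[rng.integers(4)]
            if rng.random() < 0.5:
                ref, alt = anchor + inserted, anchor + inserted + inserted
            else:
                ref, alt = anchor + inserted + inserted, anchor + inserted
            effect = "frameshift"
        else:
            ref, alt = _random_snv(rng)
            effect = "missense"
        return VariantRecord(
            chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
            frequency=frequency, gene=gene, effect=effect, clone_id=clone_id,
        )

    parental = [
        make_record(sites[i], 1.0, "parental")
        for i in range(params.n_parental_polymorphisms)
    ]
    freqs = (
        list(params.de_novo_frequencies)
        if params.de_novo_frequencies
        else [1.0] * params.n_de_novo
    )
    de_novo = [
        make_record(sites[params.n_parental_polymorphisms + i], freqs[i], "child")
        for i in range(params.n_de_novo)
    ]
    child = [
        VariantRecord(
            chrom=p.chrom, pos=p.pos, ref_allele=p.ref_allele, alt_allele=p.alt_allele,
            frequency=p.frequency, gene=p.gene, effect=p.effect, clone_id="child",
        )
        for p in parental
    ] + de_novo
    return parental, child, de_novo


def simulate_survival_assay(
    true_survival: float,
    n_cells: float = 1e8,
    dilution: float = 1e-5,
    seed: int = 0,
) -> SurvivalAssay:
    """Simulate a CFU shock-survival assay with Poisson plate counts.

    The control plate count is Poisson(n_cells * dilution); the treated
    plate is Poisson(n_cells * true_survival * dilution).
    """
    if not (0 <= true_survival <= 1):
        raise ValueError("true_survival must lie in [0, 1]")
    if n_cells <= 0 or not (0 < dilution <= 1):
        raise ValueError("n_cells must be > 0 and dilution in (0, 1]")
    rng = np.random.default_rng(seed)
    control = int(rng.poisson(n_cells * dilution))
    treated = int(rng.poisson(n_cells * true_survival * dilution))
    return SurvivalAssay(
        cfu_treated=treated,
        cfu_control=max(control, 1),  # a zero control plate would void the assay
        dilution_treated=dilution,
        dilution_control=dilution,
    )
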