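"""Associative N-fixation rates from closed-vial ``15N2`` incubations.

A sealed vial (Exetainer) holds a soil or excised-root sample. Part of the
headspace is withdrawn, replaced with ``15N2`` tracer gas, and after an
incubation of ``t`` days the sample's ``15N`` enrichment is measured by IRMS
against a paired natural-abundance control vial. The fixation rate follows
from mass balance of the heavy isotope:

    rate (ug N vial-1 d-1) = (AE_i * TN_i) / (AE_atm * t)

where ``AE_i`` is the atom-fraction excess of the sample (treatment minus
control, converted from atom percent), ``TN_i`` the total N mass in the vial
(ug), and ``AE_atm`` the atom-fraction excess of the headspace N2 after
tracer addition. ``AE_atm`` comes from equal-pressure volume bookkeeping of
the gas exchange: the tracer volume over total headspace N2, assuming the
residual air contributes N2 at its atmospheric fraction.

All enrichments are stored in instrument convention (atom percent) and
converted to atom fractions before the rate equation, so sample and
headspace excesses share units. Headspace ``AE_atm`` is deliberately not
corrected for incubation-time N2 production (e.g. by denitrification); any
such production dilutes the tracer, so rates computed this way are
conservative (biased low, never high).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "NATURAL_ABUNDANCE_15N_PCT",
    "AIR_N2_FRACTION",
    "DEFAULT_ATOM_PCT_SD",
    "IncubationVial",
    "FixationResult",
    "ContaminationSpec",
    "InvalidGeometryError",
    "DiluteTracerWarning",
    "headspace_atom_excess",
    "fixation_rate",
    "contamination_false_positive",
    "is_attributable",
]

#: Natural abundance of 15N in atmospheric N2, atom percent.
NATURAL_ABUNDANCE_15N_PCT = 0.3663

#: Volume fraction of N2 in air.
AIR_N2_FRACTION = 0.78

#: Default instrument repeatability on atom% determinations (1 SD).
DEFAULT_ATOM_PCT_SD = 0.0002

#: Packing densities used to back-derive the occupied (solid + liquid)
#: volume when it was not recorded per vial, g cm-3.
_ASSUMED_DENSITY = {"soil": 1.9, "root": 1.0}


class InvalidGeometryError(ValueError):
    """Vial volume bookkeeping is inconsistent (non-positive headspace)."""


class DiluteTracerWarning(UserWarning):
    """Headspace enrichment did not exceed natural abundance."""


@dataclass
class IncubationVial:
    """One sealed-vial ``15N2`` assay.

    Parameters
    ----------
    sample_kind : {'soil', 'root'}
    dry_mass : float
        Sample dry mass, g.
    total_n : float
        Total N in the vial (``TN_i``), ug.
    atom_pct_treatment, atom_pct_control : float
        Post-incubation atom% 15N of the tracered sample and of the
        paired natural-abundance control.
    vial_volume, occupied_volume, removed_volume, tracer_volume : float
        Vial geometry, mL. ``occupied_volume`` (solid + liquid) defaults to
        ``dry_mass`` over an assumed packing density (soil 1.9, root
        1.0 g cm-3) when not supplied. ``removed_volume`` is headspace
        withdrawn before tracer addition.
    tracer_enrichment : float
        15N atom fraction of the tracer gas, in (0, 1].
    duration : float
        Incubation time, days.
    """

    sample_kind: str
    dry_mass: float
    total_n: float
    atom_pct_treatment: float
    atom_pct_control: float
    vial_volume: float = 12.0
    occupied_volume: float | None = None
    removed_volume: float = 4.0
    tracer_volume: float = 4.2
    tracer_enrichment: float = 0.99
    duration: float = 7.0

    def __post_init__(self) -> None:
        if self.sample_kind not in ("soil", "root"):
            raise ValueError(f"sample_kind must be 'soil' or 'root', got {self.sample_kind!r}")
        if self.occupied_volume is None:
            self.occupied_volume = self.dry_mass / _ASSUMED_DENSITY[self.sample_kind]
        if not self.dry_mass > 0:
            raise ValueError("dry_mass must be positive")
        if not self.total_n > 0:
            raise ValueError("total_n must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        for name in ("atom_pct_treatment", "atom_pct_control"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be within [0, 100] atom%, got {v}")
        if not 0.0 < self.tracer_enrichment <= 1.0:
            raise ValueError("tracer_enrichment must be in (0, 1]")
        if not self.occupied_volume + self.removed_volume < self.vial_volume + self.tracer_volume:
            raise InvalidGeometryError(
                "occupied_volume + removed_volume must be smaller than "
                "vial_volume + tracer_volume"
            )

    @property
    def atom_excess_sample(self) -> float:
        """``AE_i`` as an atom fraction (may be negative for noisy controls)."""
        return (self.atom_pct_treatment - self.atom_pct_control) / 100.0


@dataclass(frozen=True)
class FixationResult:
    """Outcome of the vial rate calculation.

    ``rate_per_gram = rate_per_vial / dry_mass`` always holds; rates below
    the detection floor are zeroed in the floored fields and kept verbatim
    in ``raw_rate_per_gram``.
    """

    rate_per_vial: float  # ug N vial-1 d-1, floored
    rate_per_gram: float  # ug N g-1 d-1, floored
    ae_sample: float  # atom-fraction excess of the sample
    ae_atm: float  # atom-fraction excess of headspace N2
    below_detection: bool
    raw_rate_per_gram: float  # unfloored, sign preserved


@dataclass(frozen=True)
class ContaminationSpec:
    """Reactive-15N contamination level of a tracer gas batch.

    Commercial 15N2 can carry reactive 15N (15NH3, 15NOx) that organisms
    assimilate directly, enriching the sample without any fixation.
    """

    reactive_15n_per_ml_tracer: float  # ug reactive 15N per mL tracer gas
    forms: frozenset[str] = field(default_factory=lambda: frozenset({"NH3", "NOx"}))

    def __post_init__(self) -> None:
        if self.reactive_15n_per_ml_tracer < 0:
            raise ValueError("reactive_15n_per_ml_tracer must be >= 0")


def headspace_atom_excess(
    vial: IncubationVial,
    n2_fraction_air: float = AIR_N2_FRACTION,
    natural_abundance: float = NATURAL_ABUNDANCE_15N_PCT / 100.0,
) -> float:
    """Atom-fraction excess of headspace N2 after tracer addition.

    Equal-pressure volume bookkeeping: the headspace remaining after sample
    loading and syringe withdrawal contributes air N2 at ``n2_fraction_air``;
    the added tracer contributes pure N2 at ``tracer_enrichment``. The 15N
    fraction of the mixture, minus ``natural_abundance``, is ``AE_atm``.
    Pressure effects of over-filling the withdrawn void are ignored.

    Returns the excess clamped at 0; a non-positive pre-clamp value emits a
    :class:`DiluteTracerWarning` (tracer too dilute to enrich the vial).

    Raises
    ------
    InvalidGeometryError
        If no headspace remains after loading and withdrawal, or the final
        headspace is non-positive.
    """
    residual_air = vial.vial_volume - vial.occupied_volume - vial.removed_volume
    if residual_air < 0:
        raise InvalidGeometryError(
            f"negative residual headspace ({residual_air:.3g} mL) before tracer addition"
        )
    headspace = residual_air + vial.tracer_volume
    if headspace <= 0:
        raise InvalidGeometryError("non-positive headspace after tracer addition")
    total_n2 = vial.tracer_volume + residual_air * n2_fraction_air
    if total_n2 <= 0:
        raise InvalidGeometryError("no N2 in headspace")
    fraction_15n = vial.tracer_volume * vial.tracer_enrichment / total_n2
    ae = fraction_15n - natural_abundance
    if ae <= 0:
        warnings.warn(
            "headspace 15N does not exceed natural abundance; tracer too dilute",
            DiluteTracerWarning,
            stacklevel=2,
        )
        return 0.0
    return ae


def fixation_rate(
    vial: IncubationVial,
    ae_atm: float,
    detection_atom_pct_sd: float = DEFAULT_ATOM_PCT_SD,
) -> FixationResult:
    """Fixation rate of one vial from the isotope mass balance.

    ``rate_per_vial = AE_i * TN_i / (AE_atm * t)``, then normalized by dry
    mass. The detection floor is the rate implied by a sample excess of
    twice the instrument atom% SD: raw rates below it (including negative
    excesses, where the control out-enriched the treatment) are floored to
    zero and flagged, with the raw value retained.

    Raises
    ------
    ValueError
        If ``ae_atm`` is not positive (the rate equation divides by it).
    """
    if not ae_atm > 0:
        raise ValueError(f"ae_atm must be positive, got {ae_atm}")
    ae_i = vial.atom_excess_sample
    denom = ae_atm * vial.duration
    raw_per_vial = ae_i * vial.total_n / denom
    raw_per_gram = raw_per_vial / vial.dry_mass
    threshold_ae = 2.0 * detection_atom_pct_sd / 100.0
    threshold_rate = threshold_ae * vial.total_n / (denom * vial.dry_mass)
    below = raw_per_gram < threshold_rate
    return FixationResult(
        rate_per_vial=0.0 if below else raw_per_vial,
        rate_per_gram=0.0 if below else raw_per_gram,
        ae_sample=ae_i,
        ae_atm=ae_atm,
        below_detection=below,
        raw_rate_per_gram=raw_per_gram,
    )


def contamination_false_positive(
    vial: IncubationVial,
    spec: ContaminationSpec,
    ae_atm: float | None = None,
) -> float:
    """Worst-case apparent rate (ug N g-1 d-1) from tracer contamination.

    Assumes every microgram of reactive 15N delivered with the tracer
    (``tracer_volume * reactive_15n_per_ml_tracer``) is assimilated into the
    sample over the incubation and read back through the rate equation. A
    measured rate at or below this bound cannot be attributed to fixation.

    ``ae_atm`` defaults to :func:`headspace_atom_excess` on the vial.
    """
    if ae_atm is None:
        ae_atm = headspace_atom_excess(vial)
    if not ae_atm > 0:
        raise ValueError(f"ae_atm must be positive, got {ae_atm}")
    reactive_mass = vial.tracer_volume * spec.reactive_15n_per_ml_tracer
    return reactive_mass / (ae_atm * vial.duration * vial.dry_mass)


def is_attributable(measured_rate_per_gram: float, false_positive_bound: float) -> bool:
    """True when a measured rate exceeds the contamination bound."""
    if false_positive_bound < 0:
        raise ValueError("false_positive_bound must be >= 0")
    return measured_rate_per_gram > false_positive_bound
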