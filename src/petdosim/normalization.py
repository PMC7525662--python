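"""Rat→human organ-mass normalisation of residence times.

A rat organ occupying a given fraction of rat body mass maps onto a
human organ occupying a different fraction of human body mass.  The
per-organ scaling factor

    factor = (b_r / o_r) · (o_h / b_h)

(b = body mass, o = organ mass, r = rat, h = human) converts a rat
organ's residence time into the residence time the same *relative*
kinetics would produce in the human phantom.  Whole-body τ is not
scaled — total cumulated activity is fixed by the decay physics — and
the remainder is recomputed after organ scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ValidationError
from .phantom import OrganMassTable
from .residence import ResidenceTimeSet, _resolve_remainder


def scaling_factor(b_r: float, o_r: float, b_h: float, o_h: float) -> float:
    """(b_r/o_r)·(o_h/b_h); all masses in grams, all > 0."""
    for name, value in (("b_r", b_r), ("o_r", o_r), ("b_h", b_h), ("o_h", o_h)):
        if value <= 0:
            raise ValidationError(f"non-positive mass {name}={value}")
    return (b_r / o_r) * (o_h / b_h)


@dataclass
class ScalingFactorTable:
    """Per-organ rat→human scaling factors for one human phantom."""

    phantom: str
    factors: dict[str, float]
    provenance: dict[str, dict[str, float]]  # organ -> {b_r, o_r, b_h, o_h}

    def __post_init__(self) -> None:
        for organ, f in self.factors.items():
            if f <= 0:
                raise ValidationError(f"{organ}: non-positive scaling factor")


def build_scaling_table(
    rat: OrganMassTable, human: OrganMassTable, organs=None
) -> ScalingFactorTable:
    """Scaling factors for every organ present in both mass tables.

    With ``organs`` given, factors are computed for exactly those organs
    and a missing mass raises.
    """
    organs = sorted(
        set(rat.organ_masses) & set(human.organ_masses) if organs is None else organs
    )
    factors, prov = {}, {}
    for organ in organs:
        o_r, o_h = rat.mass(organ), human.mass(organ)
        factors[organ] = scaling_factor(rat.body_mass_g, o_r, human.body_mass_g, o_h)
        prov[organ] = {
            "b_r": rat.body_mass_g,
            "o_r": o_r,
            "b_h": human.body_mass_g,
            "o_h": o_h,
        }
    return ScalingFactorTable(phantom=human.species, factors=factors, provenance=prov)


def normalise_residence_times(
    rts: ResidenceTimeSet,
    rat: OrganMassTable,
    human: OrganMassTable,
) -> ResidenceTimeSet:
    """Scale each organ τ by its mass-normalisation factor.

    The whole-body τ is left unchanged; the remainder is recomputed as
    whole-body τ − Σ scaled organ τ (clamped/validated like the raw
    remainder).  Normalising an already-normalised set is an error.
    """
    if rts.normalised:
        raise ValidationError("residence times already normalised")
    table = build_scaling_table(rat, human, organs=rts.organs)
    scaled = {o: tau * table.factors[o] for o, tau in rts.organs.items()}
    remainder = _resolve_remainder(rts.whole_body, sum(scaled.values()))
    return replace(
        rts, organs=scaled, remainder=remainder, normalised=True
    )
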