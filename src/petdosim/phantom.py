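"""Phantom-side data: organ-mass tables, S-value matrices, tissue weights.

The package ships editable fixture tables under ``petdosim/data``:
reference organ masses for the rat and for adult male/female phantoms,
a *synthetic* (diagonally dominant, physically plausible) S-value matrix
per phantom, and an ICRP-60-style tissue-weighting scheme renormalised to
the modelled target organs.  Real phantom S-values can be supplied in the
same CSV layout to reproduce production dosimetry numerics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import MissingOrganError, ValidationError

WEIGHT_SUM_TOL = 1e-9

#: Reference total body masses (grams): mean adult rat, reference adult
#: male and female humans.
RAT_BODY_MASS_G = 332.67
HUMAN_BODY_MASS_G = {"adult_male": 73_000.0, "adult_female": 60_000.0}


@dataclass
class OrganMassTable:
    """Organ masses (grams) for one species/phantom."""

    species: str
    body_mass_g: float
    organ_masses: dict[str, float]

    def __post_init__(self) -> None:
        if self.body_mass_g <= 0:
            raise ValidationError("body mass must be positive")
        for organ, m in self.organ_masses.items():
            if m <= 0:
                raise ValidationError(f"{organ}: non-positive mass {m}")
        if sum(self.organ_masses.values()) > self.body_mass_g:
            raise ValidationError("sum of organ masses exceeds body mass")

    def mass(self, organ: str) -> float:
        try:
            return self.organ_masses[organ]
        except KeyError:
            raise MissingOrganError(
                f"organ {organ!r} missing from {self.species} mass table"
            ) from None


@dataclass
class SValueMatrix:
    """Source→target dose factors for one phantom.

    ``S`` is a DataFrame with target organs as the index and source
    organs (including ``remainder``) as columns, in mGy/(MBq·h).
    ``tissue_weights`` maps target organs to dimensionless w_T summing
    to 1; the effective dose is the w_T-weighted sum of target doses.
    """

    phantom: str
    S: pd.DataFrame
    tissue_weights: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.S = self.S.astype(float)
        self.tissue_weights = self.tissue_weights.astype(float)
        if self.S.index.has_duplicates or self.S.columns.has_duplicates:
            raise ValidationError("duplicate organ name in S-value matrix")
        if (self.S.to_numpy() < 0).any():
            raise ValidationError("negative S-value entry")
        total = float(self.tissue_weights.sum())
        if abs(total - 1.0) > WEIGHT_SUM_TOL:
            raise ValidationError(f"tissue weights sum {total:.6g} ≠ 1")
        unknown = set(self.tissue_weights.index) - set(self.S.index)
        if unknown:
            raise ValidationError(
                f"tissue weight for unknown target(s): {sorted(unknown)}"
            )

    @property
    def sources(self) -> list[str]:
        return list(self.S.columns)

    @property
    def targets(self) -> list[str]:
        return list(self.S.index)

    def require_sources(self, names) -> None:
        """Raise unless every name exists as a source column."""
        missing = [n for n in names if n not in self.S.columns]
        if missing:
            raise MissingOrganError(
                f"source organ(s) {missing} absent from {self.phantom} "
                "S-value matrix"
            )


def _data_path(name: str):
    return resources.files("petdosim.data").joinpath(name)


def load_reference_masses(which: str) -> OrganMassTable:
    """Load a bundled organ-mass fixture: 'rat', 'adult_male' or 'adult_female'."""
    from .io import read_organ_masses

    files = {
        "rat": "rat_organ_masses.csv",
        "adult_male": "adult_male_organ_masses.csv",
        "adult_female": "adult_female_organ_masses.csv",
    }
    try:
        fname = files[which]
    except KeyError:
        raise ValidationError(f"unknown mass table {which!r}") from None
    return read_organ_masses(_data_path(fname))


def load_reference_svalues(phantom: str) -> SValueMatrix:
    """Load the bundled synthetic S-value matrix for a phantom."""
    from .io import read_svalue_matrix

    if phantom not in ("adult_male", "adult_female"):
        raise ValidationError(f"unknown phantom {phantom!r}")
    return read_svalue_matrix(
        _data_path(f"svalues_{phantom}_synthetic.csv"),
        _data_path("tissue_weights.csv"),
        phantom=phantom,
    )


def load_published_model_slopes() -> pd.DataFrame:
    """Published regression results of predicted vs measured clinical doses.

    Sixteen dosimetry-model configurations (two radiotracers × phantom sex
    × normalisation × reconstruction) with slope, SEM, 95% CI, r² and the
    printed mean percent bias, from a published rat-to-human translation
    study of FDG and an ¹⁸F-labelled octreotide analogue.
    """
    df = pd.read_csv(_data_path("published_model_slopes.csv"))
    df["normalised"] = df["normalised"].astype(bool)
    return df
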