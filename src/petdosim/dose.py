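"""MIRD-schema absorbed-dose and effective-dose computation.

Absorbed dose to a target organ T is the sum over source organs S of the
cumulated activity (here residence time τ_S, h) times the S-value
S(T←S), mGy/(MBq·h):

    D_T = Σ_S τ_S · S(T←S)          [mGy/MBq]

The effective dose is the tissue-weighted sum Σ_T w_T · D_T; for
positron/photon emitters the radiation weighting factor is 1, so the
number is the same in mSv/MBq.  All joins are by organ label, never by
position, so permuting a matrix's organ order cannot change a dose.

The remainder compartment is an explicit S-matrix source column; no
phantom-internal remainder mass correction is applied (that correction
needs phantom composition data the matrix input does not carry).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .phantom import WEIGHT_SUM_TOL, OrganMassTable, SValueMatrix
from .residence import DecayConstants, ResidenceTimeSet, residence_times
from .tac import SubjectScan


@dataclass
class DoseModelConfig:
    """One of the dosimetry-model configurations: reconstruction is a
    property of the scan; normalisation and phantom sex are chosen here."""

    normalised: bool
    phantom: str  # "adult_male" | "adult_female"
    svalues: SValueMatrix
    rat_masses: OrganMassTable | None = None
    human_masses: OrganMassTable | None = None
    decay: DecayConstants = DecayConstants()

    def __post_init__(self) -> None:
        if self.normalised and (self.rat_masses is None or self.human_masses is None):
            raise ValidationError(
                "normalised model needs rat and human organ-mass tables"
            )


@dataclass
class DoseReport:
    """Absorbed doses per target (mGy/MBq) and effective dose (mSv/MBq)."""

    doses: pd.Series
    effective_dose_msv: float
    phantom: str
    reconstruction: str
    normalised: bool

    def __post_init__(self) -> None:
        if (self.doses < 0).any():
            raise ValidationError("negative absorbed dose")

    @property
    def descriptor(self) -> str:
        kind = "normalised" if self.normalised else "non-normalised"
        return f"{self.phantom}, {kind}, {self.reconstruction}"


def absorbed_doses(taus, svalues: SValueMatrix) -> pd.Series:
    """Matrix–vector MIRD sum, joined by organ label.

    ``taus`` is a mapping/Series of source organ → τ (hours), including
    the remainder.  Every τ source must exist as an S-matrix column;
    S-matrix columns without a τ contribute nothing.
    """
    tau = pd.Series(taus, dtype=float)
    if tau.index.has_duplicates:
        raise ValidationError("duplicate source organ in residence times")
    svalues.require_sources(tau.index)
    doses = svalues.S[tau.index].to_numpy() @ tau.to_numpy()
    return pd.Series(doses, index=svalues.S.index, name="dose_mGy_per_MBq")


def effective_dose(doses: pd.Series, tissue_weights: pd.Series) -> float:
    """Tissue-weighted sum Σ_T w_T·D_T, mSv/MBq (w_r = 1 for PET emissions)."""
    w = pd.Series(tissue_weights, dtype=float)
    total = float(w.sum())
    if abs(total - 1.0) > WEIGHT_SUM_TOL:
        raise ValidationError(f"tissue weights sum {total:.6g} ≠ 1")
    unknown = w.index.difference(doses.index)
    if len(unknown):
        raise ValidationError(f"weight for unknown target(s): {list(unknown)}")
    return float((w * doses.reindex(w.index)).sum())


def doses_from_residence_times(
    rts: ResidenceTimeSet, svalues: SValueMatrix
) -> DoseReport:
    doses = absorbed_doses(rts.source_taus(), svalues)
    eff = effective_dose(doses, svalues.tissue_weights)
    return DoseReport(
        doses=doses,
        effective_dose_msv=eff,
        phantom=svalues.phantom,
        reconstruction=rts.reconstruction,
        normalised=rts.normalised,
    )


def run_dosimetry_model(scan: SubjectScan, config: DoseModelConfig) -> DoseReport:
    """Full pipeline for one model: τ → (optional normalisation) → doses."""
    from .normalization import normalise_residence_times

    rts = residence_times(scan, decay=config.decay)
    if config.normalised:
        rts = normalise_residence_times(rts, config.rat_masses, config.human_masses)
    report = doses_from_residence_times(rts, config.svalues)
    report.phantom = config.phantom
    return report


def run_all_models(
    scan_fbp: SubjectScan,
    scan_iterative: SubjectScan,
    svalues_by_phantom: dict[str, SValueMatrix],
    rat_masses: OrganMassTable,
    human_masses_by_phantom: dict[str, OrganMassTable],
    decay: DecayConstants = DecayConstants(),
) -> list[DoseReport]:
    """The eight dosimetry models: {FBP, iterative} × {raw, normalised}
    × {adult_male, adult_female}."""
    reports = []
    for scan in (scan_fbp, scan_iterative):
        for normalised in (False, True):
            for phantom, sv in svalues_by_phantom.items():
                config = DoseModelConfig(
                    normalised=normalised,
                    phantom=phantom,
                    svalues=sv,
                    rat_masses=rat_masses if normalised else None,
                    human_masses=(
                        human_masses_by_phantom[phantom] if normalised else None
                    ),
                    decay=decay,
                )
                reports.append(run_dosimetry_model(scan, config))
    return reports


def rank_organs(report: DoseReport, k: int) -> list[str]:
    """Top-k targets by absorbed dose, ties broken alphabetically."""
    if k < 1:
        raise ValidationError("k must be ≥ 1")
    ordered = sorted(report.doses.items(), key=lambda kv: (-kv[1], kv[0]))
    return [organ for organ, _ in ordered[:k]]
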