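"""Seeded synthetic inputs with the statistical structure of a rodent
whole-body PET dosimetry study.

Organ kinetics follow a two-rate uptake/washout model: the biological
activity of an organ is

    A_bio(t) = 100 · f · (e^{−k_out t} − e^{−k_up t}) / peak

(peak-normalised so f is the organ's peak fraction of injected dose),
multiplied by physical decay e^{−λt} and sampled at frame midpoints with
multiplicative lognormal noise.  The whole-body curve is the physical
decay envelope reduced by a saturating excreted fraction; it never
exceeds 100 %ID.  The default kinetic spec is kidney-dominant, the
signature of peptide radiotracers cleared by glomerular filtration.

Reconstruction bias is modelled statistically: the "iterative" member of
a scan pair has its source-organ activities scaled by ρ (default 1.6),
reproducing the systematically higher residence times that iterative
reconstruction yields relative to filtered-back projection.  The
whole-body curve is not scaled, so the %ID bound and a non-negative
remainder survive scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .organs import LLI_WALL, WHOLE_BODY
from .residence import DecayConstants
from .tac import SubjectScan, TimeActivityCurve, default_frame_schedule

#: Default iterative/FBP residence-time scale.
DEFAULT_RECON_RATIO = 1.6

#: Organ-name order used for synthetic dose tables; the LLI wall comes
#: early so every table of ≥ 3 organs contains it.
DOSE_TABLE_ORGANS = (
    "kidneys",
    "liver",
    LLI_WALL,
    "urinary_bladder",
    "brain",
    "heart",
    "lungs",
    "intestine",
    "spleen",
    "pancreas",
    "stomach_wall",
    "red_marrow",
    "thyroid",
    "muscle",
    "skin",
    "bone_surface",
)


@dataclass(frozen=True)
class OrganKinetics:
    """Two-rate uptake/washout parameters for one organ.

    f : peak fraction of injected dose taken up (dimensionless)
    k_up : uptake rate, 1/min (``inf`` = instantaneous uptake)
    k_out : biological washout rate, 1/min
    """

    f: float
    k_up: float
    k_out: float

    def __post_init__(self) -> None:
        if not (0 <= self.f <= 1):
            raise ValidationError(f"uptake fraction f={self.f} outside [0, 1]")
        if self.k_up < 0 or self.k_out < 0:
            raise ValidationError("rates must be ≥ 0")
        if math.isfinite(self.k_up) and self.k_up <= self.k_out:
            raise ValidationError("k_up must exceed k_out")

    def shape(self, t_min: np.ndarray) -> np.ndarray:
        """Peak-normalised biological uptake/washout shape in [0, 1]."""
        t = np.asarray(t_min, dtype=float)
        a, b = self.k_out, self.k_up
        if not math.isfinite(b):
            return np.exp(-a * t)
        g = np.exp(-a * t) - np.exp(-b * t)
        if a == 0.0:
            peak = 1.0  # saturating uptake, asymptote 1
        else:
            t_star = math.log(b / a) / (b - a)
            peak = math.exp(-a * t_star) - math.exp(-b * t_star)
        return g / peak


@dataclass
class KineticSpec:
    """Cohort-level generating parameters for a synthetic scan pair."""

    organs: dict[str, OrganKinetics]
    recon_ratio: float = DEFAULT_RECON_RATIO
    noise_cv: float = 0.05
    excreted_max: float = 0.12   # asymptotic fraction lost from the body VOI
    excretion_rate: float = 0.02  # 1/min

    def __post_init__(self) -> None:
        if not self.organs:
            raise ValidationError("kinetic spec has no organs")
        total_f = sum(k.f for k in self.organs.values())
        if total_f > 1.0:
            raise ValidationError(f"Σ organ uptake fractions {total_f:.3g} > 1")
        if self.recon_ratio <= 0:
            raise ValidationError("recon_ratio must be positive")
        if self.noise_cv < 0:
            raise ValidationError("noise CV must be ≥ 0")
        if not (0 <= self.excreted_max < 1):
            raise ValidationError("excreted_max must lie in [0, 1)")


def default_kinetic_spec(**overrides) -> KineticSpec:
    """Kidney-dominant peptide-like kinetics (renal clearance, bladder
    accumulation, low brain/heart background)."""
    organs = {
        "kidneys": OrganKinetics(f=0.28, k_up=0.15, k_out=0.002),
        "liver": OrganKinetics(f=0.06, k_up=0.20, k_out=0.010),
        "heart": OrganKinetics(f=0.02, k_up=0.50, k_out=0.020),
        "lungs": OrganKinetics(f=0.02, k_up=0.50, k_out=0.020),
        "brain": OrganKinetics(f=0.01, k_up=0.30, k_out=0.010),
        "intestine": OrganKinetics(f=0.05, k_up=0.05, k_out=0.003),
        "urinary_bladder": OrganKinetics(f=0.10, k_up=0.02, k_out=0.0),
    }
    return KineticSpec(organs=organs, **overrides)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2), size=size)


def generate_scan(
    spec: KineticSpec,
    frame_schedule: np.ndarray | None = None,
    decay: DecayConstants = DecayConstants(),
    seed: int = 0,
    subject_id: str = "sim",
    radiotracer: str = "synthetic-peptide",
) -> tuple[SubjectScan, SubjectScan]:
    """Generate a matched (FBP, iterative) scan pair for one subject.

    Identical seeds give bit-identical scans.  The iterative scan's
    source-organ activities carry the reconstruction scale ρ, so its
    organ residence times are ≈ ρ × the FBP ones.
    """
    schedule = (
        default_frame_schedule() if frame_schedule is None else np.asarray(frame_schedule)
    )
    t_start, t_end = schedule[:, 0], schedule[:, 1]
    t_mid = 0.5 * (t_start + t_end)
    rng = np.random.default_rng(seed)
    decay_factor = np.exp(-decay.lambda_per_min * t_mid)
    envelope = 100.0 * decay_factor
    excreted = spec.excreted_max * (1.0 - np.exp(-spec.excretion_rate * t_mid))

    scans = []
    for recon, organ_scale in (("FBP", 1.0), ("iterative", spec.recon_ratio)):
        tacs = {}
        for organ, kin in spec.organs.items():
            bio = 100.0 * kin.f * kin.shape(t_mid)
            noise = _lognormal_noise(rng, spec.noise_cv, t_mid.size)
            tacs[organ] = TimeActivityCurve(
                organ=organ,
                t_start=t_start,
                t_end=t_end,
                activity=organ_scale * bio * decay_factor * noise,
                decay_corrected=False,
            )
        wb_noise = _lognormal_noise(rng, spec.noise_cv, t_mid.size)
        wb = np.minimum(envelope * (1.0 - excreted) * wb_noise, envelope)
        scans.append(
            SubjectScan(
                subject_id=subject_id,
                radiotracer=radiotracer,
                body_mass_g=float(np.round(rng.normal(443.0, 40.0), 1)),
                reconstruction=recon,
                whole_body=TimeActivityCurve(
                    organ=WHOLE_BODY,
                    t_start=t_start,
                    t_end=t_end,
                    activity=wb,
                    decay_corrected=False,
                ),
                tacs=tacs,
            )
        )
    return scans[0], scans[1]


def generate_dose_pairs(
    n_organs: int = 12,
    true_dose_range: tuple[float, float] = (0.002, 0.06),
    slope: float = 0.6,
    noise_cv: float = 0.2,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """(predicted, true) clinical dose tables with a known generating slope.

    True doses (mGy/MBq) are uniform over ``true_dose_range``; predicted
    = slope × true × multiplicative lognormal noise.  Tables are indexed
    by standard organ names and always include the LLI wall.
    """
    if slope <= 0:
        raise ValidationError("slope must be positive")
    if n_organs < 3:
        raise ValidationError("need ≥ 3 organs for a regression")
    if n_organs > len(DOSE_TABLE_ORGANS):
        raise ValidationError(
            f"at most {len(DOSE_TABLE_ORGANS)} standard organ names available"
        )
    lo, hi = true_dose_range
    if not (0 <= lo < hi):
        raise ValidationError("invalid true_dose_range")
    rng = np.random.default_rng(seed)
    organs = list(DOSE_TABLE_ORGANS[:n_organs])
    true = pd.Series(rng.uniform(lo, hi, n_organs), index=organs, name="true")
    noise = _lognormal_noise(rng, noise_cv, n_organs)
    predicted = pd.Series(
        slope * true.to_numpy() * noise, index=organs, name="predicted"
    )
    return predicted, true


def generate_fixture_bundle(
    out_dir, seed: int = 0, n_subjects: int = 3
) -> dict[str, Path]:
    """Write a complete worked dataset to ``out_dir``.

    Contents: per-subject FBP/iterative TAC files, rat and human
    organ-mass tables, the synthetic S-value matrices with tissue
    weights, and synthetic clinical reference dose tables for two
    radiotracers.  Regenerating with the same seed gives identical files.
    """
    from .io import (
        write_dose_table,
        write_organ_masses,
        write_svalue_matrix,
        write_tac_file,
    )
    from .phantom import load_reference_masses, load_reference_svalues

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    files: dict[str, Path] = {}

    spec = default_kinetic_spec()
    for i in range(n_subjects):
        sid = f"s{i + 1:02d}"
        sub_seed = int(root.integers(0, 2**31 - 1))
        fbp, itr = generate_scan(spec, seed=sub_seed, subject_id=sid)
        for scan in (fbp, itr):
            name = f"tac_{sid}_{scan.reconstruction}.csv"
            files[name] = write_tac_file(scan, out / name)

    for which in ("rat", "adult_male", "adult_female"):
        name = f"{which}_organ_masses.csv"
        files[name] = write_organ_masses(load_reference_masses(which), out / name)

    for phantom in ("adult_male", "adult_female"):
        sv = load_reference_svalues(phantom)
        sname = f"svalues_{phantom}_synthetic.csv"
        write_svalue_matrix(sv, out / sname, out / "tissue_weights.csv")
        files[sname] = out / sname
    files["tissue_weights.csv"] = out / "tissue_weights.csv"

    # synthetic clinical reference doses (true clinical measurements are
    # not redistributable; these only exercise the bias pipeline)
    for tracer in ("FDG", "OC"):
        _, true = generate_dose_pairs(
            n_organs=8, seed=int(root.integers(0, 2**31 - 1))
        )
        name = f"clinical_doses_{tracer}_synthetic.csv"
        files[name] = write_dose_table(
            true, out / name,
            meta={"radiotracer": tracer, "seed": seed,
                  "note": "synthetic clinical reference doses"},
        )
    return files
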