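"""Readers and writers for the package's delimited-text formats.

All formats are plain CSV with an optional leading metadata block of
``# key: value`` lines (YAML syntax behind the ``#``), so every file is
self-contained and survives a round trip bit-exactly on activity values.

Formats
-------
TAC file
    columns ``organ,t_start_min,t_end_min,pct_id`` plus metadata keys
    ``subject_id, radiotracer, body_mass_g, reconstruction,
    decay_corrected`` (and optional ``injected_activity_mbq``).
Organ masses
    columns ``organ,mass_g`` plus metadata ``species, body_mass_g``.
S-value matrix
    row labels = target organs, column labels = source organs,
    cells in mGy/(MBq·h); tissue weights in a separate
    ``organ,w_T`` file.
Residence times
    columns ``organ,tau_h`` (incl. ``whole_body`` and ``remainder`` rows)
    plus metadata ``reconstruction, normalised``.
Dose tables
    columns ``organ,dose_mGy_per_MBq``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .errors import FrameScheduleError, MissingOrganError, ValidationError
from .organs import REMAINDER, WHOLE_BODY, canonical_organ
from .phantom import OrganMassTable, SValueMatrix
from .tac import SubjectScan, TimeActivityCurve

TAC_COLUMNS = ["organ", "t_start_min", "t_end_min", "pct_id"]


def _read_metadata(path) -> dict:
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                lines.append(line[1:].strip())
            elif line.strip():
                break
    meta = yaml.safe_load("\n".join(lines)) if lines else None
    return meta if isinstance(meta, dict) else {}


def _write_metadata(fh, meta: dict) -> None:
    for key, value in meta.items():
        if value is not None:
            fh.write(f"# {key}: {value}\n")


# ---------------------------------------------------------------- TAC files


def read_tac_file(path) -> SubjectScan:
    """Read a subject scan from a TAC CSV.

    Organ labels are canonicalised; paired organs (left/right kidney or
    lung) are summed into the single phantom organ.  The file must
    contain a whole-body curve and at least one source organ, all on one
    frame schedule.
    """
    meta = _read_metadata(path)
    for key in ("subject_id", "reconstruction", "decay_corrected"):
        if key not in meta:
            raise ValidationError(f"{path}: metadata key {key!r} missing")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing_cols = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing column(s) {missing_cols}")

    decay_corrected = bool(meta["decay_corrected"])
    inj = meta.get("injected_activity_mbq")
    curves: dict[str, TimeActivityCurve] = {}
    df["organ"] = df["organ"].map(canonical_organ)
    for organ, grp in df.groupby("organ", sort=False):
        # paired VOIs (e.g. left+right kidney) collapse onto one canonical
        # organ: require a shared schedule, sum the activities
        grp = grp.sort_values(["t_start_min", "t_end_min"], kind="stable")
        key = grp[["t_start_min", "t_end_min"]].apply(tuple, axis=1)
        summed = grp.groupby(key.values, sort=True).agg(
            t_start_min=("t_start_min", "first"),
            t_end_min=("t_end_min", "first"),
            pct_id=("pct_id", "sum"),
            n=("pct_id", "size"),
        )
        if summed["n"].nunique() > 1:
            raise FrameScheduleError(
                f"{organ}: paired VOIs do not share one frame schedule"
            )
        curves[organ] = TimeActivityCurve(
            organ=organ,
            t_start=summed["t_start_min"].to_numpy(),
            t_end=summed["t_end_min"].to_numpy(),
            activity=summed["pct_id"].to_numpy(),
            decay_corrected=decay_corrected,
            injected_activity_mbq=inj,
        )
    if WHOLE_BODY not in curves:
        raise MissingOrganError(f"{path}: no whole-body curve")
    whole_body = curves.pop(WHOLE_BODY)
    if not curves:
        raise ValidationError(f"{path}: no source-organ curves")
    return SubjectScan(
        subject_id=str(meta["subject_id"]),
        radiotracer=str(meta.get("radiotracer", "unknown")),
        body_mass_g=meta.get("body_mass_g"),
        reconstruction=str(meta["reconstruction"]),
        whole_body=whole_body,
        tacs=curves,
    )


def write_tac_file(scan: SubjectScan, path) -> Path:
    """Write a subject scan; ``read_tac_file`` reproduces it bit-exactly."""
    path = Path(path)
    rows = []
    for tac in scan.all_curves():
        for ts, te, a in zip(tac.t_start, tac.t_end, tac.activity):
            rows.append((tac.organ, ts, te, a))
    df = pd.DataFrame(rows, columns=TAC_COLUMNS)
    with open(path, "w") as fh:
        _write_metadata(
            fh,
            {
                "subject_id": scan.subject_id,
                "radiotracer": scan.radiotracer,
                "body_mass_g": scan.body_mass_g,
                "reconstruction": scan.reconstruction,
                "decay_corrected": str(scan.decay_corrected).lower(),
                "injected_activity_mbq": scan.whole_body.injected_activity_mbq,
            },
        )
        # 17 significant digits round-trip float64 exactly
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


# ------------------------------------------------------------- mass tables


def read_organ_masses(path) -> OrganMassTable:
    meta = _read_metadata(path)
    for key in ("species", "body_mass_g"):
        if key not in meta:
            raise ValidationError(f"{path}: metadata key {key!r} missing")
    df = pd.read_csv(path, comment="#")
    organs = df["organ"].map(canonical_organ)
    if organs.duplicated().any():
        raise ValidationError(f"{path}: duplicate organ name")
    return OrganMassTable(
        species=str(meta["species"]),
        body_mass_g=float(meta["body_mass_g"]),
        organ_masses=dict(zip(organs, df["mass_g"].astype(float))),
    )


def write_organ_masses(table: OrganMassTable, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        _write_metadata(
            fh, {"species": table.species, "body_mass_g": table.body_mass_g}
        )
        pd.Series(table.organ_masses, name="mass_g").rename_axis("organ").to_csv(fh)
    return path


# ---------------------------------------------------------- S-value matrix


def read_svalue_matrix(path, weights_path, phantom: str = "custom") -> SValueMatrix:
    """Load an S-value matrix (targets × sources) and its tissue weights."""
    with open(path) as fh:
        S = pd.read_csv(fh, index_col=0, comment="#")
    wdf = pd.read_csv(weights_path, comment="#")
    if wdf["organ"].duplicated().any():
        raise ValidationError(f"{weights_path}: duplicate organ name")
    weights = pd.Series(
        wdf.iloc[:, 1].to_numpy(dtype=float), index=wdf["organ"], name="w_T"
    )
    return SValueMatrix(phantom=phantom, S=S, tissue_weights=weights)


def write_svalue_matrix(sv: SValueMatrix, path, weights_path) -> None:
    sv.S.rename_axis("target").to_csv(path)
    sv.tissue_weights.rename_axis("organ").to_csv(weights_path)


# -------------------------------------------------- residence times, doses


def write_residence_times(rts, path) -> Path:
    """Serialise a ResidenceTimeSet as organ,tau_h CSV with metadata."""
    path = Path(path)
    rows = dict(rts.organs)
    rows[REMAINDER] = rts.remainder
    rows[WHOLE_BODY] = rts.whole_body
    with open(path, "w") as fh:
        _write_metadata(
            fh,
            {
                "reconstruction": rts.reconstruction,
                "normalised": str(rts.normalised).lower(),
            },
        )
        pd.Series(rows, name="tau_h").rename_axis("organ").to_csv(fh)
    return path


def read_residence_times(path):
    from .residence import ResidenceTimeSet

    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", index_col=0)
    tau = df["tau_h"].astype(float)
    if WHOLE_BODY not in tau.index or REMAINDER not in tau.index:
        raise ValidationError(f"{path}: whole_body/remainder row missing")
    organs = {o: float(v) for o, v in tau.items() if o not in (WHOLE_BODY, REMAINDER)}
    return ResidenceTimeSet(
        organs=organs,
        whole_body=float(tau[WHOLE_BODY]),
        remainder=float(tau[REMAINDER]),
        reconstruction=str(meta.get("reconstruction", "unknown")),
        normalised=bool(meta.get("normalised", False)),
    )


def read_dose_table(path) -> pd.Series:
    """Read an ``organ,dose_mGy_per_MBq`` table as a Series indexed by organ."""
    df = pd.read_csv(path, comment="#")
    if df["organ"].duplicated().any():
        raise ValidationError(f"{path}: duplicate organ name")
    s = pd.Series(
        df.iloc[:, 1].to_numpy(dtype=float),
        index=df["organ"].map(canonical_organ),
        name="dose_mGy_per_MBq",
    )
    if (s < 0).any():
        raise ValidationError(f"{path}: negative dose")
    return s


def write_dose_table(doses: pd.Series, path, meta: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if meta:
            _write_metadata(fh, meta)
        doses.rename("dose_mGy_per_MBq").rename_axis("organ").to_csv(fh)
    return path
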