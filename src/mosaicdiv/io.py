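"""Readers/writers for the occurrence, survey and species tables; run config.

File conventions (all delimited text, UTF-8, "." decimal, comma default):

* occurrence table — first column survey id, remaining columns one per
  species, cells 0/1 (abundances accepted with ``binarize=True``);
* survey table — columns ``survey_id, lon, lat, protection, pa_id``
  followed by any number of numeric environmental columns;
* species table — columns ``species_id, iucn`` (optional file; species
  absent from it are treated as not assessed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    OccurrenceMatrix,
    SpeciesInfo,
    Survey,
    ValidationError,
)

__all__ = ["read_dataset", "write_dataset", "RunConfig", "load_config", "file_digest"]

logger = logging.getLogger(__name__)


def read_dataset(
    occurrence_path: str | Path,
    survey_path: str | Path,
    species_path: str | Path | None = None,
    delimiter: str = ",",
    binarize: bool = False,
) -> tuple[OccurrenceMatrix, list[Survey], list[SpeciesInfo]]:
    """Read and cross-validate the three input tables.

    Every occurrence row must have a survey-metadata row; surveys listed
    in the metadata but absent from the occurrence table are kept with an
    all-zero row (warning). Species missing from the species table get no
    IUCN status. With ``binarize=True`` any positive cell is coerced to 1
    with a warning (all analyses are incidence-based); otherwise a
    non-binary cell is a hard error naming the row and column.
    """
    occ_raw = pd.read_csv(occurrence_path, sep=delimiter, index_col=0)
    occ_raw.index = occ_raw.index.astype(str)
    occ_raw.columns = occ_raw.columns.astype(str)

    values = occ_raw.to_numpy()
    if not np.issubdtype(np.asarray(values).dtype, np.number):
        bad = occ_raw.map(lambda v: not isinstance(v, (int, float, np.number)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell at survey {occ_raw.index[r]!r}, "
            f"species {occ_raw.columns[c]!r}"
        )
    if binarize:
        nonbinary = ~np.isin(values, (0, 1))
        if nonbinary.any():
            logger.warning(
                "binarized %d abundance cell(s) (any value > 0 -> 1)",
                int(nonbinary.sum()),
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative cell at survey {occ_raw.index[r]!r}, "
                f"species {occ_raw.columns[c]!r}"
            )
        occ_raw = (occ_raw > 0).astype(np.int8)

    surv_raw = pd.read_csv(survey_path, sep=delimiter, dtype={"survey_id": str})
    required = {"survey_id", "lon", "lat", "protection"}
    missing_cols = required - set(surv_raw.columns)
    if missing_cols:
        raise ValidationError(f"survey table missing columns: {sorted(missing_cols)}")
    if surv_raw["survey_id"].duplicated().any():
        dups = surv_raw.loc[surv_raw["survey_id"].duplicated(), "survey_id"].tolist()
        raise ValidationError(f"duplicate survey ids in metadata: {dups}")

    meta_cols = {"survey_id", "lon", "lat", "protection", "pa_id"}
    env_cols = [c for c in surv_raw.columns if c not in meta_cols]
    surveys: list[Survey] = []
    for _, row in surv_raw.iterrows():
        pa_id = row.get("pa_id")
        if pd.isna(pa_id) or pa_id == "":
            pa_id = None
        env = {c: float(row[c]) for c in env_cols}
        surveys.append(
            Survey(
                survey_id=str(row["survey_id"]),
                lon=row["lon"],
                lat=row["lat"],
                protection=str(row["protection"]),
                pa_id=pa_id,
                env=env,
            )
        )

    survey_ids = [s.survey_id for s in surveys]
    unknown_rows = set(occ_raw.index) - set(survey_ids)
    if unknown_rows:
        raise ValidationError(
            f"occurrence rows without survey metadata: {sorted(unknown_rows)}"
        )
    absent = [sid for sid in survey_ids if sid not in occ_raw.index]
    if absent:
        logger.warning(
            "%d survey(s) absent from the occurrence table kept with all-zero "
            "rows: %s",
            len(absent),
            absent,
        )
        zeros = pd.DataFrame(
            0, index=pd.Index(absent), columns=occ_raw.columns, dtype=np.int8
        )
        occ_raw = pd.concat([occ_raw, zeros])
    occ = OccurrenceMatrix(occ_raw.loc[survey_ids])

    species: list[SpeciesInfo] = []
    by_id: dict[str, SpeciesInfo] = {}
    if species_path is not None:
        sp_raw = pd.read_csv(species_path, sep=delimiter, dtype=str)
        if "species_id" not in sp_raw.columns:
            raise ValidationError("species table missing column 'species_id'")
        if sp_raw["species_id"].duplicated().any():
            dups = sp_raw.loc[sp_raw["species_id"].duplicated(), "species_id"].tolist()
            raise ValidationError(f"duplicate species ids: {dups}")
        for _, row in sp_raw.iterrows():
            iucn = row.get("iucn")
            if pd.isna(iucn) or iucn in ("", "none"):
                iucn = None
            info = SpeciesInfo(species_id=str(row["species_id"]), iucn=iucn)
            by_id[info.species_id] = info
    for sid in occ.species:
        species.append(by_id.get(sid, SpeciesInfo(species_id=sid, iucn=None)))

    logger.info(
        "read dataset: %d surveys x %d species (%d IUCN-assessed)",
        *occ.shape,
        sum(1 for sp in species if sp.iucn is not None),
    )
    return occ, surveys, species


def write_dataset(
    out_dir: str | Path,
    occ: OccurrenceMatrix,
    surveys: Sequence[Survey],
    species: Sequence[SpeciesInfo],
    delimiter: str = ",",
) -> dict[str, Path]:
    """Write the three tables; inverse of :func:`read_dataset`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrence": out / "occurrence.csv",
        "surveys": out / "surveys.csv",
        "species": out / "species.csv",
    }
    frame = occ.to_frame()
    frame.index.name = "survey_id"
    frame.to_csv(paths["occurrence"], sep=delimiter)

    env_cols = sorted({k for s in surveys for k in s.env})
    rows = []
    for s in surveys:
        row = {
            "survey_id": s.survey_id,
            "lon": s.lon,
            "lat": s.lat,
            "protection": s.protection,
            "pa_id": s.pa_id if s.pa_id is not None else "",
        }
        for c in env_cols:
            row[c] = s.env.get(c, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["surveys"], sep=delimiter, index=False)

    pd.DataFrame(
        [
            {"species_id": sp.species_id, "iucn": sp.iucn if sp.iucn else ""}
            for sp in species
        ]
    ).to_csv(paths["species"], sep=delimiter, index=False)
    return paths


@dataclass
class RunConfig:
    """Pipeline run configuration (YAML-serializable)."""

    buffer_km: list[float] = field(default_factory=lambda: [50.0])
    n_subsample_iter: int = 199
    n_null: int = 199
    n_perm: int = 999
    min_occurrence: int = 1
    seed: int = 0
    env_vars: list[str] | None = None
    #: paths to input tables; None -> simulate
    occurrence: str | None = None
    surveys: str | None = None
    species: str | None = None
    #: GeneratorParams overrides used when no input paths are given
    simulate: dict | None = None

    def __post_init__(self) -> None:
        if isinstance(self.buffer_km, (int, float)):
            self.buffer_km = [float(self.buffer_km)]
        self.buffer_km = [float(b) for b in self.buffer_km]
        for name in ("n_subsample_iter", "n_null", "n_perm"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.min_occurrence < 1:
            raise ValidationError("min_occurrence must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def file_digest(path: str | Path) -> str:
    """SHA-256 digest of a file, for the run manifest."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
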