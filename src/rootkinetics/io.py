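"""Plain-text table I/O.

All tables are comma-separated UTF-8 with a header row, '.' decimal and
units embedded in column names.  Schemas:

* ``particles.csv`` — root_id, x_start_um, x_end_um, dt_h
* ``cellfile.csv`` — root_id, file_side, cell_index, length_um, qc_offset_um
* ``ploidy.csv`` — sample_id, genotype, intensity
* ``truth.json`` — the growth-zone parameters plus derived quantities
* ``static_summary.csv``, ``kinematics_summary.csv``, ``regr_profile.csv``,
  ``ploidy_proportions.csv``, ``ploidy_tests.csv`` — result tables
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .growthzone import GrowthZoneSpec
from .ploidy import PloidyProportions
from .synthetic import (
    PLOIDY_CLASSES,
    CellLengthProfile,
    ParticleObservations,
    PloidySample,
)

__all__ = [
    "read_particles_csv",
    "write_particles_csv",
    "read_cellfile_csv",
    "write_cellfile_csv",
    "read_ploidy_csv",
    "write_ploidy_csv",
    "write_truth_json",
    "read_truth_json",
    "write_proportions_csv",
]

_FLOAT_FMT = "%.6f"


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ParameterError(f"{path}: missing columns {sorted(missing)}")


def write_particles_csv(
    path, observations: Iterable[ParticleObservations]
) -> None:
    frames = [o.records for o in observations]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_particles_csv(path, position_noise_sd: float = 0.0) -> list[ParticleObservations]:
    """Read particle records, one :class:`ParticleObservations` per root."""
    df = pd.read_csv(path)
    _require_columns(df, ["root_id", "x_start_um", "x_end_um", "dt_h"], path)
    return [
        ParticleObservations(g.reset_index(drop=True), position_noise_sd=position_noise_sd)
        for _, g in df.groupby("root_id", sort=True)
    ]


def write_cellfile_csv(path, profiles: Iterable[CellLengthProfile]) -> None:
    rows = []
    for p in profiles:
        for i, length in enumerate(p.lengths, start=1):
            rows.append(
                {
                    "root_id": p.root_id,
                    "file_side": p.file_side,
                    "cell_index": i,
                    "length_um": length,
                    "qc_offset_um": p.qc_offset,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cellfile_csv(path) -> list[CellLengthProfile]:
    """Read cell files, one profile per (root_id, file_side), ordered by cell_index."""
    df = pd.read_csv(path)
    _require_columns(
        df, ["root_id", "file_side", "cell_index", "length_um", "qc_offset_um"], path
    )
    out = []
    for (rid, side), g in df.groupby(["root_id", "file_side"], sort=True):
        g = g.sort_values("cell_index")
        if not (g["cell_index"].to_numpy() == np.arange(1, len(g) + 1)).all():
            raise ParameterError(f"{path}: cell_index not contiguous for {rid}/{side}")
        out.append(
            CellLengthProfile(
                root_id=str(rid),
                file_side=str(side),
                lengths=g["length_um"].to_numpy(float),
                qc_offset=float(g["qc_offset_um"].iloc[0]),
            )
        )
    return out


def write_ploidy_csv(path, samples: Iterable[PloidySample]) -> None:
    frames = [
        pd.DataFrame(
            {
                "sample_id": s.sample_id,
                "genotype": s.genotype,
                "intensity": s.intensities,
            }
        )
        for s in samples
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_ploidy_csv(path) -> list[PloidySample]:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "genotype", "intensity"], path)
    return [
        PloidySample(
            sample_id=str(sid),
            genotype=str(g["genotype"].iloc[0]),
            intensities=g["intensity"].to_numpy(float),
        )
        for sid, g in df.groupby("sample_id", sort=True)
    ]


def write_truth_json(path, spec: GrowthZoneSpec) -> None:
    """Write the full growth-zone parameterization and derived quantities."""
    payload = {
        "spec": asdict(spec),
        "derived": {
            "growth_zone_length_um": spec.growth_zone_length,
            "final_velocity_um_h": spec.final_velocity,
            "cell_production_per_h": spec.cell_production,
            "mature_cell_length_um": spec.mature_cell_length,
            "meristem_cell_count": spec.meristem_cell_count,
            "cell_cycle_duration_h": spec.cell_cycle_duration,
        },
        "units": {"position": "um", "time": "h"},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth_json(path) -> GrowthZoneSpec:
    payload = json.loads(Path(path).read_text())
    return GrowthZoneSpec(**payload["spec"])


def write_proportions_csv(path, props: Iterable[PloidyProportions]) -> None:
    rows = []
    for p in props:
        row = {"sample_id": p.sample_id, "genotype": p.genotype, "n": p.n_total}
        row.update({f"p{c}": p.proportions[c] for c in PLOIDY_CLASSES})
        row["anchor"] = p.anchor_used
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
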