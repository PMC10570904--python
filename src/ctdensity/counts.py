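"""Daily count table: the repeated-count data structure for N-mixture fits.

Counts ``y[s, i, j, t]`` hold the number of individuals of species *s*
annotated at site *i* during 24-h survey day *j* of year *t*, summed over
all sequences of that day.  An effort mask records which site-days had an
active camera; counts are identically zero off the mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import HexGrid, assign_sites
from .io import Deployment, SequenceRecord

__all__ = ["CountTable", "build_count_table"]


@dataclass
class CountTable:
    """Species x site x day x year daily counts with an effort mask."""

    counts: np.ndarray        # (S, R, J, T) non-negative ints
    effort: np.ndarray        # (R, J, T) bool
    species: list[str]
    site_ids: list[int]       # grid cell ids, length R
    site_coords: np.ndarray   # (R, 2) centroid km
    years: list[int]          # year indices, length T

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.effort = np.asarray(self.effort, dtype=bool)
        if self.counts.shape[1:] != self.effort.shape:
            raise ValueError("counts and effort shapes disagree")
        if np.any(self.counts[:, ~self.effort]):
            raise ValueError("non-zero count off the effort mask")
        if np.any(self.counts < 0):
            raise ValueError("negative count")

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]

    @property
    def n_days(self) -> int:
        return self.counts.shape[2]

    @property
    def n_years(self) -> int:
        return self.counts.shape[3]

    def total_individuals(self) -> int:
        return int(self.counts.sum())

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per (species, site, day, year)."""
        S, R, J, T = self.counts.shape
        sp, si, dj, yt = np.meshgrid(
            np.arange(S), np.arange(R), np.arange(J), np.arange(T), indexing="ij"
        )
        return pd.DataFrame(
            {
                "species": np.asarray(self.species)[sp.ravel()],
                "site": np.asarray(self.site_ids)[si.ravel()],
                "day": dj.ravel() + 1,
                "year": np.asarray(self.years)[yt.ravel()],
                "count": self.counts.ravel(),
                "effort": self.effort[si.ravel(), dj.ravel(), yt.ravel()].astype(int),
            }
        )

    def save(self, directory: str | Path) -> None:
        """Write ``counts.csv`` (long format) + ``meta.json`` sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_long_frame().to_csv(directory / "counts.csv", index=False)
        meta = {
            "species": self.species,
            "site_ids": self.site_ids,
            "site_coords": self.site_coords.tolist(),
            "years": self.years,
            "n_days": self.n_days,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "CountTable":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        df = pd.read_csv(directory / "counts.csv")
        S = len(meta["species"])
        R = len(meta["site_ids"])
        J = meta["n_days"]
        T = len(meta["years"])
        s_idx = pd.Categorical(df["species"], categories=meta["species"]).codes
        i_idx = pd.Categorical(df["site"], categories=meta["site_ids"]).codes
        j_idx = df["day"].to_numpy() - 1
        t_idx = pd.Categorical(df["year"], categories=meta["years"]).codes
        counts = np.zeros((S, R, J, T), dtype=np.int64)
        counts[s_idx, i_idx, j_idx, t_idx] = df["count"].to_numpy()
        effort = np.zeros((R, J, T), dtype=bool)
        effort[i_idx, j_idx, t_idx] = df["effort"].to_numpy().astype(bool)
        return cls(
            counts=counts,
            effort=effort,
            species=list(meta["species"]),
            site_ids=list(meta["site_ids"]),
            site_coords=np.asarray(meta["site_coords"], dtype=float),
            years=list(meta["years"]),
        )


def build_count_table(
    sequences: Sequence[SequenceRecord],
    deployments: Sequence[Deployment],
    grid: HexGrid,
    day_origin: int = 0,
    out_of_window: str = "reject",
    species: Sequence[str] | None = None,
) -> CountTable:
    """Aggregate sequences into daily counts on the site grid.

    Survey days are 24-h blocks anchored at local midnight plus
    ``day_origin`` hours, counted from the earliest deployment start of
    each year.  A sequence timestamped outside its camera's deployment
    window is rejected (default) or clipped into the window with a
    warning (``out_of_window="clip"``).
    """
    if out_of_window not in ("reject", "clip"):
        raise ValueError("out_of_window must be 'reject' or 'clip'")
    dep_ids = {d.camera_id for d in deployments}
    seq_ids = {s.camera_id for s in sequences}
    if not seq_ids <= dep_ids:
        raise ValueError(
            f"sequences reference cameras without deployments: {sorted(seq_ids - dep_ids)}"
        )

    camera_to_cell = assign_sites(deployments, grid)
    site_ids = sorted(set(camera_to_cell.values()))
    site_index = {cell: k for k, cell in enumerate(site_ids)}
    years = sorted({d.year_index for d in deployments})
    year_index = {y: k for k, y in enumerate(years)}

    def _anchor(ts: pd.Timestamp) -> pd.Timestamp:
        floored = ts.normalize() + pd.Timedelta(hours=day_origin)
        return floored if floored <= ts else floored - pd.Timedelta(days=1)

    year_anchor = {
        y: _anchor(min(d.start for d in deployments if d.year_index == y))
        for y in years
    }

    def _day(ts: pd.Timestamp, year: int) -> int:
        return int((ts - year_anchor[year]) // pd.Timedelta(days=1))

    # per-year survey duration: last day touched by any deployment
    J = 1 + max(_day(d.end, d.year_index) for d in deployments)

    R, T = len(site_ids), len(years)
    effort = np.zeros((R, J, T), dtype=bool)
    for d in deployments:
        i = site_index[camera_to_cell[d.camera_id]]
        t = year_index[d.year_index]
        j0, j1 = _day(d.start, d.year_index), _day(d.end, d.year_index)
        effort[i, j0 : j1 + 1, t] = True

    if species is None:
        species = sorted({s.species for s in sequences})
    species = list(species)
    s_index = {sp: k for k, sp in enumerate(species)}

    by_camera: dict[str, list[Deployment]] = {}
    for d in deployments:
        by_camera.setdefault(d.camera_id, []).append(d)

    counts = np.zeros((len(species), R, J, T), dtype=np.int64)
    for seq in sequences:
        deps = by_camera[seq.camera_id]
        dep = next((d for d in deps if d.start <= seq.start_time <= d.end), None)
        ts = seq.start_time
        if dep is None:
            if out_of_window == "reject":
                continue
            # clip to the nearest window of this camera
            dep = min(
                deps,
                key=lambda d: min(
                    abs(ts - d.start), abs(ts - d.end)
                ),
            )
            ts = min(max(ts, dep.start), dep.end)
            warnings.warn(
                f"sequence at {seq.start_time} clipped into deployment window "
                f"of camera {seq.camera_id!r}",
                stacklevel=2,
            )
        if seq.species not in s_index:
            continue
        s = s_index[seq.species]
        i = site_index[camera_to_cell[seq.camera_id]]
        t = year_index[dep.year_index]
        j = _day(ts, dep.year_index)
        counts[s, i, j, t] += seq.n_individuals

    coords = np.asarray([grid.centroids[c] for c in site_ids], dtype=float)
    return CountTable(
        counts=counts,
        effort=effort,
        species=species,
        site_ids=site_ids,
        site_coords=coords,
        years=years,
    )
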