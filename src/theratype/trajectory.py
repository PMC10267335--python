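"""Residue–ligand contact statistics from MD trajectory distance series.

Gating-competent CFTR keeps its two nucleotide-binding domains clamped
around an ATP + Mg2+ complex.  Two scalar distances track that clamp:

* ``lambda`` — backbone amide nitrogen of residue 551 to the ATP
  gamma-phosphate phosphorus (contact threshold 5 Å),
* ``sigma`` — alpha carbon of residue 1291 to the bound Mg2+ ion
  (contact threshold 7 Å).

A frame is "in contact" when the distance is strictly below the metric's
threshold; the fraction of frames in contact (occupancy) summarises how
stable the binding mode is across replicate simulations.  Occupancy is
pooled frame-weighted over replicates: it is the fraction of all simulation
data in contact, not the mean of per-replicate fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomSelector",
    "ContactMetricSpec",
    "DistanceSeries",
    "ContactSummary",
    "LAMBDA_METRIC",
    "SIGMA_METRIC",
    "distance_series_from_models",
    "read_distance_csv",
    "contact_fraction",
    "pooled_contact_fraction",
    "summarize_distances",
]


@dataclass(frozen=True)
class AtomSelector:
    """Selects exactly one atom per model of a multi-model structure.

    Any field left as ``None`` is not constrained.  The combination must
    resolve to a single atom in every model; anything else is an error,
    never a silent first-match.
    """

    atom_name: str | None = None
    res_id: int | None = None
    res_name: str | None = None
    chain_id: str | None = None
    element: str | None = None

    def describe(self) -> str:
        parts = [
            f"{k}={v}"
            for k, v in (
                ("chain", self.chain_id),
                ("res_id", self.res_id),
                ("res_name", self.res_name),
                ("atom", self.atom_name),
                ("element", self.element),
            )
            if v is not None
        ]
        return "/".join(parts) or "<any atom>"

    def mask(self, atoms) -> np.ndarray:
        m = np.ones(atoms.array_length(), dtype=bool)
        if self.atom_name is not None:
            m &= atoms.atom_name == self.atom_name
        if self.res_id is not None:
            m &= atoms.res_id == self.res_id
        if self.res_name is not None:
            m &= atoms.res_name == self.res_name
        if self.chain_id is not None:
            m &= atoms.chain_id == self.chain_id
        if self.element is not None:
            m &= atoms.element == self.element
        return m


@dataclass(frozen=True)
class ContactMetricSpec:
    """One residue–ligand distance metric with its contact threshold (Å)."""

    name: str
    atom_a: AtomSelector
    atom_b: AtomSelector
    threshold: float

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if self.atom_a == self.atom_b:
            raise ValueError("atom_a and atom_b must differ")


#: Residue 551 backbone amide N — ATP gamma-phosphate P, contact below 5 Å.
LAMBDA_METRIC = ContactMetricSpec(
    name="lambda",
    atom_a=AtomSelector(res_id=551, atom_name="N"),
    atom_b=AtomSelector(res_name="ATP", atom_name="PG"),
    threshold=5.0,
)

#: Residue 1291 alpha carbon — Mg2+ ion, contact below 7 Å.
SIGMA_METRIC = ContactMetricSpec(
    name="sigma",
    atom_a=AtomSelector(res_id=1291, atom_name="CA"),
    atom_b=AtomSelector(element="MG"),
    threshold=7.0,
)


@dataclass
class DistanceSeries:
    """Time-ordered distances (Å) for one metric in one trajectory replicate."""

    metric: ContactMetricSpec
    replicate_id: str
    times: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise ValueError(
                f"times ({self.times.size}) and distances "
                f"({self.distances.size}) differ in length"
            )
        if self.times.size < 1:
            raise ValueError("distance series must contain at least one frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.distances < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n_frames(self) -> int:
        return int(self.distances.size)


@dataclass
class ContactSummary:
    """Pooled contact-occupancy and distance statistics for one metric."""

    metric: str
    threshold: float
    per_replicate_fraction: list[float]
    pooled_fraction: float
    mean_distance: float
    sd_distance: float
    per_replicate_mean: list[float] = field(default_factory=list)
    n_frames_total: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [self.metric],
                "threshold_angstrom": [self.threshold],
                "pooled_fraction": [self.pooled_fraction],
                "mean_distance_angstrom": [self.mean_distance],
                "sd_distance_angstrom": [self.sd_distance],
                "n_frames_total": [self.n_frames_total],
            }
        )


def _resolve_atom(model, selector: AtomSelector, frame_index: int) -> np.ndarray:
    mask = selector.mask(model)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"model {frame_index}: no atom matches selector {selector.describe()}"
        )
    if n > 1:
        raise ValueError(
            f"model {frame_index}: selector {selector.describe()} "
            f"matches {n} atoms, expected exactly one"
        )
    return model.coord[mask][0]


def distance_series_from_models(
    models,
    spec: ContactMetricSpec,
    frame_times: Sequence[float] | None = None,
    replicate_id: str = "rep1",
) -> DistanceSeries:
    """Euclidean distance between the metric's two atoms in every model.

    Parameters
    ----------
    models
    A biotite ``AtomArrayStack`` (multi-model structure) or a path to a
    multi-model PDB file with MODEL/ENDMDL records.
    spec
    Distance metric: two single-atom selectors plus a contact threshold.
    frame_times
    Simulation time (ns) per model.  Defaults to 0, 1, 2, … ns; a frame
    count mismatch with the model count is an error.
    """
    if isinstance(models, (str,)) or hasattr(models, "__fspath__"):
        import biotite.structure.io.pdb as pdb

        models = pdb.PDBFile.read(str(models)).get_structure()
    n_models = models.stack_depth()
    if frame_times is None:
        frame_times = np.arange(n_models, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size != n_models:
        raise ValueError(
            f"{frame_times.size} frame times given for {n_models} models"
        )
    distances = np.empty(n_models)
    for i in range(n_models):
        model = models[i]
        a = _resolve_atom(model, spec.atom_a, i)
        b = _resolve_atom(model, spec.atom_b, i)
        distances[i] = float(np.linalg.norm(a - b))
    return DistanceSeries(
        metric=spec, replicate_id=replicate_id, times=frame_times,
        distances=distances,
    )


def read_distance_csv(path, spec: ContactMetricSpec) -> list[DistanceSeries]:
    """Read tabular distance series (time_ns, distance_angstrom, replicate_id,
    metric) and return one series per replicate, filtered to ``spec.name``."""
    df = pd.read_csv(path)
    required = {"time_ns", "distance_angstrom", "replicate_id", "metric"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"distance CSV missing columns: {sorted(missing)}")
    df = df[df["metric"] == spec.name]
    if df.empty:
        raise ValueError(f"no rows for metric {spec.name!r} in {path}")
    out = []
    for rep, grp in df.groupby("replicate_id", sort=True):
        grp = grp.sort_values("time_ns")
        out.append(
            DistanceSeries(
                metric=spec,
                replicate_id=str(rep),
                times=grp["time_ns"].to_numpy(),
                distances=grp["distance_angstrom"].to_numpy(),
            )
        )
    return out


def contact_fraction(series: DistanceSeries, threshold: float | None = None) -> float:
    """Fraction of frames with distance strictly below the threshold.

    Ties at exactly the threshold count as not-in-contact.  Defaults to the
    series' own metric threshold.
    """
    if threshold is None:
        threshold = series.metric.threshold
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if series.n_frames == 0:
        raise ValueError("empty distance series")
    return float(np.count_nonzero(series.distances < threshold) / series.n_frames)


def _check_same_metric(series_list: Sequence[DistanceSeries]) -> ContactMetricSpec:
    if len(series_list) == 0:
        raise ValueError("need at least one distance series")
    metric = series_list[0].metric
    for s in series_list[1:]:
        if s.metric.name != metric.name:
            raise ValueError(
                f"mixed metrics: {metric.name!r} and {s.metric.name!r}"
            )
    return metric


def pooled_contact_fraction(
    series_list: Sequence[DistanceSeries], threshold: float | None = None
) -> float:
    """Frame-weighted occupancy over all replicates.

    Computed as (total frames below threshold) / (total frames) over the
    concatenated replicates — the fraction of all simulation data in
    contact — which differs from the mean of per-replicate fractions when
    replicate lengths differ.
    """
    metric = _check_same_metric(series_list)
    if threshold is None:
        threshold = metric.threshold
    below = sum(np.count_nonzero(s.distances < threshold) for s in series_list)
    total = sum(s.n_frames for s in series_list)
    return float(below / total)


def summarize_distances(series_list: Sequence[DistanceSeries]) -> ContactSummary:
    """Pooled mean ± sample SD distance and occupancy fractions for one metric.

    Mean and SD are over all frames pooled across replicates; per-replicate
    means and fractions are also reported since either convention is common
    in trajectory analyses.
    """
    metric = _check_same_metric(series_list)
    pooled = np.concatenate([s.distances for s in series_list])
    per_frac = [contact_fraction(s, metric.threshold) for s in series_list]
    sd = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
    return ContactSummary(
        metric=metric.name,
        threshold=metric.threshold,
        per_replicate_fraction=per_frac,
        pooled_fraction=pooled_contact_fraction(series_list, metric.threshold),
        mean_distance=float(np.mean(pooled)),
        sd_distance=sd,
        per_replicate_mean=[float(np.mean(s.distances)) for s in series_list],
        n_frames_total=int(pooled.size),
    )
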