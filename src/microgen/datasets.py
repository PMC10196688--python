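"""Longitudinal microbiome data containers and preprocessing.

A cohort is a subject x timepoint x taxon tensor of relative abundances
(RA, per-sample proportions summing to 1) plus a binary observation mask:
mask[s, i] = 0 means the sample of subject s at timepoint i was never
collected and is stored as an all-zero vector.  Preprocessing replaces
zeros with a pseudo-count (half of the smallest nonzero RA in the whole
cohort) and applies the centered log-ratio (clr) transform so downstream
models operate on unconstrained real values.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalDataset",
    "ClrDataset",
    "TimeGapPair",
    "ImputationResult",
    "load_dataset",
    "add_pseudocount",
    "clr_transform",
    "clr_with_pseudocount",
    "compute_time_gaps",
    "time_gaps",
]


class MicrogenError(ValueError):
    """Raised for invalid inputs anywhere in the package."""


@dataclasses.dataclass
class LongitudinalDataset:
    """Masked longitudinal relative-abundance tensor.

    Attributes
    ----------
    abundances : ndarray, shape (S, k, n)
        Relative abundances in [0, 1]; missing samples are all-zero rows.
    timepoints : ndarray, shape (k,)
        Strictly increasing study times (e.g. months).
    mask : ndarray, shape (S, k)
        1 where the sample was observed, 0 where missing.
    taxon_ids, phylum : lists of n strings.
    subject_ids : list of S strings.
    pseudo_count : float or None
        Recorded when :func:`add_pseudocount` produced this dataset.
    """

    abundances: np.ndarray
    timepoints: np.ndarray
    mask: np.ndarray
    taxon_ids: list
    phylum: list
    subject_ids: list
    pseudo_count: float | None = None

    @property
    def n_subjects(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.abundances.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.abundances.shape[2]

    def validate(self, atol: float = 1e-6) -> None:
        x, e = self.abundances, self.mask
        if x.ndim != 3:
            raise MicrogenError("abundance tensor must be 3-dimensional")
        if e.shape != x.shape[:2]:
            raise MicrogenError("mask shape does not match abundances")
        if not np.all((e == 0) | (e == 1)):
            raise MicrogenError("mask must be binary")
        if np.any(np.diff(self.timepoints) <= 0):
            raise MicrogenError("timepoints must be strictly increasing")
        if np.any(x < 0):
            raise MicrogenError("abundances must be nonnegative")
        sums = x.sum(axis=2)
        obs = e == 1
        if obs.any() and np.max(np.abs(sums[obs] - 1.0)) > atol:
            raise MicrogenError("observed samples must sum to 1")
        if (~obs).any() and np.max(np.abs(sums[~obs])) > 0:
            raise MicrogenError("missing samples must be stored as zeros")

    def copy(self) -> "LongitudinalDataset":
        return LongitudinalDataset(
            self.abundances.copy(), self.timepoints.copy(), self.mask.copy(),
            list(self.taxon_ids), list(self.phylum), list(self.subject_ids),
            self.pseudo_count,
        )


@dataclasses.dataclass
class ClrDataset:
    """Centered log-ratio transformed cohort; missing samples remain zero rows."""

    clr_values: np.ndarray
    pseudo_count: float
    source: LongitudinalDataset

    @property
    def mask(self) -> np.ndarray:
        return self.source.mask


@dataclasses.dataclass
class TimeGapPair:
    """Per-subject forward/backward elapsed time since the nearest observed sample."""

    delta_f: np.ndarray
    delta_b: np.ndarray


@dataclasses.dataclass
class ImputationResult:
    """Observed-value-preserving imputation on the clr scale.

    ``ra_values`` is the post-processed relative-abundance twin, filled in
    lazily by :func:`microgen.metrics.postprocess_to_ra`.
    """

    clr_values: np.ndarray
    mask: np.ndarray
    method: str
    ra_values: np.ndarray | None = None


def _parse_phylum(lineage: str) -> str:
    """Extract the phylum token from a Greengenes-style lineage, else use as-is."""
    if "p__" in lineage:
        for part in lineage.split(";"):
            part = part.strip()
            if part.startswith("p__"):
                return part[3:].strip()
        return ""
    if ";" in lineage or lineage.strip().startswith("k__"):
        return ""
    return lineage.strip()


def load_dataset(table_path, metadata_path, taxonomy_path) -> LongitudinalDataset:
    """Read an OTU table (TSV, taxa x samples), sample metadata and taxonomy.

    Metadata columns: sample_id, subject_id, timepoint.  Taxonomy columns:
    taxon_id plus either a ``lineage`` string containing ``p__<Phylum>`` or a
    bare ``phylum`` column.  Samples listed in the metadata but absent from
    the table get mask 0; columns are total-sum normalized.
    """
    table = pd.read_csv(table_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    taxo = pd.read_csv(taxonomy_path, sep="\t", dtype=str)

    if meta.duplicated(subset=["subject_id", "timepoint"]).any():
        dup = meta[meta.duplicated(subset=["subject_id", "timepoint"], keep=False)]
        raise MicrogenError(
            f"duplicate (subject, timepoint) pairs in metadata: "
            f"{sorted(set(zip(dup.subject_id, dup.timepoint)))}"
        )

    taxo = taxo.set_index(taxo.columns[0])
    phylum_col = "phylum" if "phylum" in taxo.columns else "lineage"
    phylum_of = {}
    for taxon in table.index:
        if taxon not in taxo.index:
            raise MicrogenError(f"taxon {taxon!r} missing from the taxonomy file")
        phylum_of[taxon] = _parse_phylum(str(taxo.loc[taxon, phylum_col]))

    subject_ids = sorted(meta.subject_id.unique())
    timepoints = np.sort(meta.timepoint.astype(float).unique())
    taxon_ids = list(table.index.astype(str))
    s, k, n = len(subject_ids), len(timepoints), len(taxon_ids)
    x = np.zeros((s, k, n))
    e = np.zeros((s, k), dtype=int)
    t_index = {t: i for i, t in enumerate(timepoints)}
    s_index = {sid: i for i, sid in enumerate(subject_ids)}

    for _, row in meta.iterrows():
        if row.sample_id not in table.columns:
            continue  # missing sample: mask stays 0
        col = table[row.sample_id].to_numpy(dtype=float)
        total = col.sum()
        if not np.isfinite(total) or total <= 0:
            raise MicrogenError(f"sample column {row.sample_id!r} is not sum-normalizable")
        si, ti = s_index[row.subject_id], t_index[float(row.timepoint)]
        x[si, ti] = col / total
        e[si, ti] = 1

    ds = LongitudinalDataset(
        abundances=x, timepoints=timepoints, mask=e, taxon_ids=taxon_ids,
        phylum=[phylum_of[t] for t in table.index], subject_ids=subject_ids,
    )
    ds.validate()
    return ds


def add_pseudocount(ds: LongitudinalDataset) -> LongitudinalDataset:
    """Replace zeros in observed samples by half the global minimum nonzero RA.

    One global pseudo-count is used for the whole cohort so the
    zero-restoration threshold in post-processing is well defined; each
    observed sample is renormalized to sum to 1 afterwards.
    """
    obs = ds.mask == 1
    vals = ds.abundances[obs]
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise MicrogenError("dataset has no nonzero observed entries")
    c = float(nonzero.min()) / 2.0
    x = ds.abundances.copy()
    xo = x[obs]
    xo[xo == 0] = c
    xo /= xo.sum(axis=1, keepdims=True)
    x[obs] = xo
    return LongitudinalDataset(
        x, ds.timepoints.copy(), ds.mask.copy(), list(ds.taxon_ids),
        list(ds.phylum), list(ds.subject_ids), pseudo_count=c,
    )


def clr_transform(ds: LongitudinalDataset) -> ClrDataset:
    """Centered log-ratio transform of every observed sample (natural log).

    clr_j = ln x_j - mean_m ln x_m; missing samples stay zero vectors.
    """
    if ds.pseudo_count is None:
        raise MicrogenError("apply add_pseudocount before clr_transform")
    obs = ds.mask == 1
    if np.any(ds.abundances[obs] <= 0):
        raise MicrogenError("observed entries must be strictly positive for clr")
    clr = np.zeros_like(ds.abundances)
    logs = np.log(ds.abundances[obs])
    clr[obs] = logs - logs.mean(axis=1, keepdims=True)
    return ClrDataset(clr_values=clr, pseudo_count=ds.pseudo_count, source=ds)


def clr_with_pseudocount(ds: LongitudinalDataset, pseudo_count: float) -> ClrDataset:
    """clr transform with an externally fixed pseudo-count.

    Used to put ground-truth samples on the same clr scale as a pipeline
    whose pseudo-count was estimated from the masked (training) data.
    """
    obs = ds.mask == 1
    x = ds.abundances.copy()
    xo = x[obs]
    xo[xo == 0] = pseudo_count
    xo /= xo.sum(axis=1, keepdims=True)
    x[obs] = xo
    with_c = LongitudinalDataset(
        x, ds.timepoints, ds.mask, ds.taxon_ids, ds.phylum, ds.subject_ids,
        pseudo_count=pseudo_count,
    )
    return clr_transform(with_c)


def compute_time_gaps(timepoints: Sequence[float],
                      mask_row: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Forward/backward time gaps for one subject.

    delta_f[i] is the elapsed time since the most recent observed sample
    before i (accumulating across runs of missing samples); delta_b is the
    mirror image from the end of the series.
    """
    t = np.asarray(timepoints, dtype=float)
    e = np.asarray(mask_row, dtype=int)
    k = t.size
    if k == 0:
        raise MicrogenError("empty timepoint sequence")
    if e.size != k:
        raise MicrogenError("mask length does not match timepoints")
    df = np.zeros(k)
    for i in range(1, k):
        df[i] = t[i] - t[i - 1] + (0.0 if e[i - 1] == 1 else df[i - 1])
    db = np.zeros(k)
    for i in range(k - 2, -1, -1):
        db[i] = t[i + 1] - t[i] + (0.0 if e[i + 1] == 1 else db[i + 1])
    return df, db


def time_gaps(ds: LongitudinalDataset) -> TimeGapPair:
    """Stack :func:`compute_time_gaps` over all subjects."""
    rows = [compute_time_gaps(ds.timepoints, ds.mask[s]) for s in range(ds.n_subjects)]
    return TimeGapPair(
        delta_f=np.stack([r[0] for r in rows]),
        delta_b=np.stack([r[1] for r in rows]),
    )
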