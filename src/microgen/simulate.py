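"""Synthetic longitudinal microbiome cohorts and missingness mechanisms.

The generator emulates the statistical structure an infant-gut cohort
study provides: compositional samples with subject-specific structural
zeros, within-phylum correlation (taxa in the same phylum share a drift
process), and smooth temporal trajectories (log-scale AR(1) dynamics).
`perturb_subjects` then follows the template-perturbation recipe used to
expand a cohort: tiny Gaussian noise added to each nonzero taxon with the
net perturbation re-balanced so zeros are preserved and every sample
still sums to one.

`ampute` removes whole samples under MCAR, MAR or MNAR.  MAR/MNAR use the
weighted-sum-score mechanism: per-timepoint summary variables (mean clr
per sample) are standardized, scored with a linear combination in which
to-be-amputed variables (MAR) or to-be-observed variables (MNAR) get
weight 0, and converted to amputation probabilities by a logistic curve
whose offset is tuned by bisection to hit the requested rate.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .datasets import LongitudinalDataset, MicrogenError, add_pseudocount

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "MissingnessSpec",
    "generate_base_cohort",
    "perturb_subjects",
    "ampute",
]


@dataclasses.dataclass
class SimulationSpec:
    n_taxa: int = 60
    n_phyla: int = 4
    n_timepoints: int = 8
    n_template_subjects: int = 30
    n_simulated_subjects: int = 0
    sparsity: float = 0.3
    ar_coefficient: float = 0.9
    innovation_sd: float = 1.0
    phylum_drift_sd: float = 0.6
    noise_mean_range: tuple = (1e-6, 2e-6)
    noise_sd: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        for f in ("n_taxa", "n_phyla", "n_timepoints", "n_template_subjects"):
            if getattr(self, f) <= 0:
                raise MicrogenError(f"{f} must be positive")
        if not 0.0 <= self.sparsity < 1.0:
            raise MicrogenError("sparsity must be in [0, 1)")
        if not 0.0 < self.ar_coefficient <= 1.0:
            raise MicrogenError("ar_coefficient must be in (0, 1]")
        if self.noise_mean_range[0] > self.noise_mean_range[1]:
            raise MicrogenError("noise_mean_range must be ordered")


@dataclasses.dataclass
class MissingnessSpec:
    mechanism: str = "MCAR"
    rate: float = 0.2
    patterns: list | None = None
    weights: np.ndarray | None = None
    score_steepness: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.mechanism not in ("MCAR", "MAR", "MNAR"):
            raise MicrogenError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 <= self.rate < 1.0:
            raise MicrogenError("rate must be in [0, 1)")


def _phylum_labels(n_taxa: int, n_phyla: int) -> list:
    """Assign taxa to phyla in contiguous, roughly equal blocks."""
    names = [f"Phylum_{chr(ord('A') + i)}" for i in range(n_phyla)]
    sizes = np.full(n_phyla, n_taxa // n_phyla)
    sizes[: n_taxa % n_phyla] += 1
    return [names[i] for i, sz in enumerate(sizes) for _ in range(sz)]


def generate_base_cohort(spec: SimulationSpec) -> LongitudinalDataset:
    """Fully observed cohort with phylum-structured, AR(1)-smooth trajectories.

    Per subject: a sparse Dirichlet baseline composition on its
    non-structurally-zero taxa; log-abundance offsets follow an AR(1)
    process (coefficient ``ar_coefficient``, innovation sd
    ``innovation_sd``) plus a shared per-phylum drift with sd
    ``phylum_drift_sd`` that makes taxa of one phylum co-vary.
    Compositions are renormalized at every timepoint; structural zeros
    stay zero across the whole series.
    """
    rng = np.random.default_rng(spec.seed)
    s, k, n = spec.n_template_subjects, spec.n_timepoints, spec.n_taxa
    phylum = _phylum_labels(n, spec.n_phyla)
    phylum_idx = np.array([ord(p[-1]) - ord("A") for p in phylum])
    n_zero = int(round(spec.sparsity * n))
    if n - n_zero < 2:
        raise MicrogenError("sparsity leaves fewer than 2 nonzero taxa")
    timepoints = 4.0 + 3.0 * np.arange(k)  # months
    x = np.zeros((s, k, n))
    for si in range(s):
        zero_taxa = rng.choice(n, size=n_zero, replace=False)
        support = np.setdiff1d(np.arange(n), zero_taxa)
        base = np.zeros(n)
        base[support] = rng.dirichlet(np.ones(support.size))
        z = np.zeros(n)
        drift = np.zeros(spec.n_phyla)
        for t in range(k):
            if t > 0:
                z = spec.ar_coefficient * z + rng.normal(0.0, spec.innovation_sd, n)
                drift = (spec.ar_coefficient * drift
                         + rng.normal(0.0, spec.phylum_drift_sd, spec.n_phyla))
            comp = np.zeros(n)
            comp[support] = base[support] * np.exp(z[support] + drift[phylum_idx[support]])
            x[si, t] = comp / comp.sum()
    ds = LongitudinalDataset(
        abundances=x, timepoints=timepoints, mask=np.ones((s, k), dtype=int),
        taxon_ids=[f"OTU_{i:04d}" for i in range(n)], phylum=phylum,
        subject_ids=[f"S{si:03d}" for si in range(s)],
    )
    ds.validate()
    return ds


def perturb_subjects(template: LongitudinalDataset, n_new: int,
                     spec: SimulationSpec) -> LongitudinalDataset:
    """New subjects as noise-perturbed copies of random template subjects.

    Each nonzero entry receives additive Gaussian noise with sd
    ``noise_sd`` and a mean drawn once per run uniformly from
    ``noise_mean_range``; the net perturbation is re-distributed in equal
    proportion across the nonzero taxa so zeros are preserved and each
    sample still sums to 1 exactly.
    """
    if n_new <= 0:
        raise MicrogenError("n_new must be positive")
    if np.any(template.mask == 0):
        raise MicrogenError("template must be fully observed")
    rng = np.random.default_rng(spec.seed + 1)
    mu = rng.uniform(*spec.noise_mean_range)
    s, k, n = template.abundances.shape
    floor = 1e-12
    x = np.zeros((n_new, k, n))
    for j in range(n_new):
        src = rng.integers(s)
        for t in range(k):
            sample = template.abundances[src, t].copy()
            nz = sample > 0
            noise = rng.normal(mu, spec.noise_sd, nz.sum())
            sample[nz] += noise - noise.sum() / nz.sum()  # re-balance to sum 1
            if np.any(sample[nz] <= 0):
                vals = np.clip(sample[nz], floor, None)
                sample[nz] = vals / vals.sum()
            x[j, t] = sample
    ds = LongitudinalDataset(
        abundances=x, timepoints=template.timepoints.copy(),
        mask=np.ones((n_new, k), dtype=int), taxon_ids=list(template.taxon_ids),
        phylum=list(template.phylum),
        subject_ids=[f"SIM{j:03d}" for j in range(n_new)],
    )
    ds.validate()
    return ds


def _mean_log(ds: LongitudinalDataset) -> np.ndarray:
    """Per-sample summary variable: mean log abundance after pseudo-counting.

    This is the location term the clr transform subtracts; the centered
    clr values themselves average to zero within every sample, so the
    pre-centering mean log is the natural scalar summary of a sample.
    """
    pc = add_pseudocount(ds)
    return np.log(pc.abundances + (pc.abundances == 0)).mean(axis=2)


def _mcar(e: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random sample removal of an exact-size subset.

    A repair step guarantees every subject keeps at least one observed
    sample by moving the amputation to another uniformly chosen candidate.
    """
    s, k = e.shape
    total = s * k
    n_remove = int(round(rate * total))
    order = rng.permutation(total)
    removed = np.zeros(total, dtype=bool)
    removed[order[:n_remove]] = True
    grid = removed.reshape(s, k)
    spare = list(order[n_remove:])
    for si in range(s):
        if grid[si].all():
            keep = rng.integers(k)
            grid[si, keep] = False
            while spare:
                cand = spare.pop(0)
                ci, cj = divmod(cand, k)
                if not grid[ci, cj] and not (grid[ci].sum() == k - 1):
                    grid[ci, cj] = True
                    break
    return (e == 1) & ~grid


def ampute(ds: LongitudinalDataset, mspec: MissingnessSpec) -> LongitudinalDataset:
    """Apply MCAR/MAR/MNAR whole-sample missingness to a fully observed cohort.

    Returns a new dataset (the input, with its ground truth, is left
    untouched).  For MAR/MNAR subjects are split uniformly among the
    missingness patterns; a subject's amputation probability is a
    logistic function of its weighted-sum score over standardized
    per-sample summary variables, with the offset bisected so the
    expected overall missing-sample fraction equals ``rate``.
    """
    if np.any(ds.mask == 0):
        raise MicrogenError("ampute expects a fully observed dataset")
    s, k = ds.mask.shape
    rng = np.random.default_rng(mspec.seed)
    if mspec.rate == 0.0:
        return ds.copy()

    if mspec.mechanism == "MCAR":
        new_mask = _mcar(ds.mask, mspec.rate, rng).astype(int)
    else:
        patterns = mspec.patterns
        if patterns is None:
            patterns = [list(range(0, k, 2)), list(range(1, k, 2))]
        if len(patterns) == 0:
            raise MicrogenError("need at least one missingness pattern")
        v = _mean_log(ds)
        v = (v - v.mean(axis=0)) / np.where(v.std(axis=0) == 0, 1.0, v.std(axis=0))
        weights = (np.ones(k) if mspec.weights is None
                   else np.asarray(mspec.weights, dtype=float))
        assignment = rng.integers(len(patterns), size=s)
        scores = np.zeros(s)
        pattern_sizes = np.zeros(s)
        for si in range(s):
            pat = np.asarray(patterns[assignment[si]], dtype=int)
            pattern_sizes[si] = len(pat)
            if mspec.mechanism == "MNAR":
                active = pat  # amputed variables carry the weight
            else:
                active = np.setdiff1d(np.arange(k), pat)  # observed variables only
            scores[si] = weights[active] @ v[si, active]
        a = mspec.score_steepness

        def realized(c: float) -> float:
            p = 1.0 / (1.0 + np.exp(-(a * scores + c)))
            return float((p * pattern_sizes).sum() / (s * k))

        lo, hi = -50.0, 50.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if realized(mid) < mspec.rate:
                lo = mid
            else:
                hi = mid
        c = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp(-(a * scores + c)))
        hit = rng.random(s) < p
        new_mask = np.ones((s, k), dtype=int)
        for si in np.flatnonzero(hit):
            new_mask[si, np.asarray(patterns[assignment[si]], dtype=int)] = 0
        for si in range(s):
            if new_mask[si].sum() == 0:
                new_mask[si, -1] = 1  # keep the last sample observed
                logger.warning("subject %s would lose all samples; kept the last",
                               ds.subject_ids[si])

    x = ds.abundances.copy()
    x[new_mask == 0] = 0.0
    out = LongitudinalDataset(
        abundances=x, timepoints=ds.timepoints.copy(), mask=new_mask,
        taxon_ids=list(ds.taxon_ids), phylum=list(ds.phylum),
        subject_ids=list(ds.subject_ids), pseudo_count=ds.pseudo_count,
    )
    out.validate()
    return out
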