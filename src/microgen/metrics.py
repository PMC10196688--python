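"""Imputation scoring: clr-MAE, RA post-processing, diversity and zero metrics.

The clr-scale MAE over missing samples is the headline comparison metric.
Post-processing maps clr output back to relative abundances (softmax),
restores zeros by thresholding at the recorded pseudo-count, and
redistributes the removed mass equally over the remaining nonzero taxa so
every sample sums to one again.  Alpha diversity uses the Shannon index,
beta diversity the Bray-Curtis distance, with paired t-tests and Pearson
correlations comparing truth against imputation over missing samples, and
an NMDS embedding of the pooled distance matrix returned as coordinates.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis, pdist, squareform
from skbio.diversity.alpha import shannon as _skbio_shannon
from sklearn.manifold import MDS

from .baselines import BASELINE_METHODS, BaselineSpec, impute_baseline
from .datasets import (ImputationResult, LongitudinalDataset, MicrogenError,
                       add_pseudocount, clr_transform, clr_with_pseudocount,
                       time_gaps)

__all__ = [
    "EvaluationReport",
    "mae_clr",
    "postprocess_to_ra",
    "shannon_index",
    "bray_curtis",
    "diversity_comparison",
    "zero_metrics",
    "benchmark",
    "BenchmarkResult",
]

GAN_METHODS = ("gan_full", "gan_bigan", "gan_rnn")


@dataclasses.dataclass
class EvaluationReport:
    """Per-method evaluation metrics over the missing samples."""

    method: str
    mae_clr: float
    mae_ra: float | None = None
    shannon_true: np.ndarray | None = None
    shannon_imputed: np.ndarray | None = None
    alpha_t_stat: float | None = None
    alpha_t_pvalue: float | None = None
    alpha_pearson_r: float | None = None
    bray_curtis_corr: float | None = None
    zero_symdiff: int | None = None
    zero_recall: float | None = None
    nmds_coords: np.ndarray | None = None
    nmds_stress: float | None = None


def mae_clr(true_clr: np.ndarray, imputed_clr: np.ndarray,
            mask: np.ndarray) -> float:
    """Mean absolute error over every (missing sample, taxon) entry."""
    true_clr = np.asarray(true_clr, dtype=float)
    imputed_clr = np.asarray(imputed_clr, dtype=float)
    if true_clr.shape != imputed_clr.shape:
        raise MicrogenError("shape mismatch between truth and imputation")
    miss = np.asarray(mask) == 0
    if not miss.any():
        raise MicrogenError("no missing samples to score")
    return float(np.mean(np.abs(true_clr[miss] - imputed_clr[miss])))


def postprocess_to_ra(imputed_clr: np.ndarray, pseudo_count: float) -> np.ndarray:
    """Scale clr values back to relative abundances with zero restoration.

    Per sample: RA proportional to exp(clr), normalized to 1; entries
    below the pseudo-count are set to zero and the resulting deficit is
    partitioned equally over the remaining nonzero taxa.
    """
    clr = np.asarray(imputed_clr, dtype=float)
    flat = clr.reshape(-1, clr.shape[-1])
    out = np.empty_like(flat)
    for i, row in enumerate(flat):
        z = row - row.max()
        ra = np.exp(z)
        ra /= ra.sum()
        below = ra < pseudo_count
        if below.all():
            raise MicrogenError("all entries fall below the pseudo-count")
        deficit = ra[below].sum()
        ra[below] = 0.0
        nnz = int((~below).sum())
        ra[~below] += deficit / nnz
        out[i] = ra
    return out.reshape(clr.shape)


def shannon_index(ra_sample: np.ndarray) -> float:
    """Shannon alpha diversity -sum_{x>0} x ln x (natural log)."""
    ra = np.asarray(ra_sample, dtype=float)
    ra = ra[ra > 0]
    return float(_skbio_shannon(ra, base=np.e))


def bray_curtis(ra_a: np.ndarray, ra_b: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) in [0, 1]."""
    return float(braycurtis(np.asarray(ra_a, dtype=float),
                            np.asarray(ra_b, dtype=float)))


def zero_metrics(true_ra: np.ndarray, imputed_ra: np.ndarray,
                 mask: np.ndarray) -> tuple[int, float | None]:
    """Symmetric difference and recall of zero-RA sets over missing samples."""
    miss = np.asarray(mask) == 0
    t = np.asarray(true_ra)[miss] == 0
    p = np.asarray(imputed_ra)[miss] == 0
    symdiff = int(np.sum(t ^ p))
    n_true = int(t.sum())
    recall = None if n_true == 0 else float(np.sum(t & p) / n_true)
    return symdiff, recall


def diversity_comparison(true_ra: np.ndarray, imputed_ra: np.ndarray,
                         mask: np.ndarray, seed: int = 0) -> dict:
    """Alpha/beta diversity agreement between truth and imputation.

    Over missing samples: paired t-test and Pearson correlation of
    Shannon values; Pearson correlation of the upper triangles of the two
    Bray-Curtis matrices; 2-D NMDS coordinates of the pooled (true +
    imputed) distance matrix, with stress.
    """
    miss = np.asarray(mask) == 0
    t_samples = np.asarray(true_ra)[miss]
    i_samples = np.asarray(imputed_ra)[miss]
    m = t_samples.shape[0]
    if m < 3:
        raise MicrogenError("need at least 3 missing samples for diversity comparison")
    sh_t = np.array([shannon_index(r) for r in t_samples])
    sh_i = np.array([shannon_index(r) for r in i_samples])
    if np.allclose(sh_t, sh_i):
        t_stat, t_p = 0.0, 1.0  # degenerate: identical diversities
        r_alpha = 1.0
    else:
        t_stat, t_p = stats.ttest_rel(sh_t, sh_i)
        r_alpha = float(stats.pearsonr(sh_t, sh_i).statistic)
    bc_t = pdist(t_samples, metric="braycurtis")
    bc_i = pdist(i_samples, metric="braycurtis")
    if np.allclose(bc_t, bc_i):
        r_beta = 1.0
    elif bc_t.std() == 0 or bc_i.std() == 0:
        r_beta = np.nan
    else:
        r_beta = float(stats.pearsonr(bc_t, bc_i).statistic)
    pooled = np.vstack([t_samples, i_samples])
    dist = squareform(pdist(pooled, metric="braycurtis"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)  # MDS API transition
        nmds = MDS(n_components=2, metric=False, dissimilarity="precomputed",
                   random_state=seed, normalized_stress="auto", n_init=4)
        coords = nmds.fit_transform(dist)
    return {
        "alpha_t_stat": float(t_stat),
        "alpha_t_pvalue": float(t_p),
        "alpha_pearson_r": r_alpha,
        "bray_curtis_corr": r_beta,
        "shannon_true": sh_t,
        "shannon_imputed": sh_i,
        "nmds_coords": coords,
        "nmds_stress": float(nmds.stress_),
    }


def evaluate(true_ds: LongitudinalDataset, result: ImputationResult,
             pseudo_count: float, seed: int = 0,
             with_diversity: bool = True) -> EvaluationReport:
    """Full metric suite for one imputation against the ground truth."""
    true_clr = clr_with_pseudocount(
        _as_fully_observed(true_ds), pseudo_count).clr_values
    mae = mae_clr(true_clr, result.clr_values, result.mask)
    imput_ra = postprocess_to_ra(result.clr_values, pseudo_count)
    result.ra_values = imput_ra
    miss = result.mask == 0
    mae_ra = float(np.mean(np.abs(true_ds.abundances[miss] - imput_ra[miss])))
    symdiff, recall = zero_metrics(true_ds.abundances, imput_ra, result.mask)
    report = EvaluationReport(method=result.method, mae_clr=mae, mae_ra=mae_ra,
                              zero_symdiff=symdiff, zero_recall=recall)
    if with_diversity and miss.sum() >= 3:
        div = diversity_comparison(true_ds.abundances, imput_ra, result.mask,
                                   seed=seed)
        for key, value in div.items():
            setattr(report, key, value)
    return report


def _as_fully_observed(ds: LongitudinalDataset) -> LongitudinalDataset:
    out = ds.copy()
    out.mask = np.ones_like(out.mask)
    return out


@dataclasses.dataclass
class BenchmarkResult:
    """Cross-validated MAE comparison across imputation methods."""

    per_fold: pd.DataFrame
    pseudo_counts: list

    @property
    def mean_mae(self) -> pd.Series:
        return self.per_fold.groupby("method").mae_clr.mean()

    def summary(self) -> str:
        means = self.mean_mae.sort_values()
        lines = ["Cross-validated clr-MAE (lower is better)", "-" * 42]
        for method, value in means.items():
            lines.append(f"{method:<16s} {value:8.4f}")
        return "\n".join(lines)


def benchmark(truth: LongitudinalDataset, methods, folds: int = 10,
              seed: int = 0, eval_timepoints=None,
              base_mask: np.ndarray | None = None,
              training_config=None) -> BenchmarkResult:
    """Cross-validated imputation comparison with test subjects masked.

    Subjects are split into ``folds`` groups; per fold, the test
    subjects' samples at ``eval_timepoints`` (default: all interior
    timepoints) are masked on top of ``base_mask``, every method imputes
    the masked cohort, and the clr-MAE against the ground truth is
    recorded.  ``methods`` may contain baseline names, ``gan_full`` /
    ``gan_bigan`` / ``gan_rnn``, or ``(name, callable)`` pairs where the
    callable maps (ClrDataset, mask) to an ImputationResult.
    """
    from .model import MicrobiomeGANImputer, TrainingConfig

    s, k = truth.mask.shape
    if folds > s:
        raise MicrogenError("more folds than subjects")
    if np.any(truth.mask == 0):
        raise MicrogenError("benchmark needs a fully observed ground-truth cohort")
    if eval_timepoints is None:
        eval_timepoints = np.arange(1, k - 1)
    eval_timepoints = np.asarray(eval_timepoints, dtype=int)
    if base_mask is None:
        base_mask = np.ones((s, k), dtype=int)
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(s) % folds
    records = []
    pseudo_counts = []
    for fold in range(folds):
        test_subjects = np.flatnonzero(assignment == fold)
        mask = base_mask.copy()
        mask[np.ix_(test_subjects, eval_timepoints)] = 0
        for si in range(s):  # never leave a subject with no observed sample
            if mask[si].sum() == 0:
                mask[si, 0] = 1
        masked = truth.copy()
        masked.mask = mask
        masked.abundances = truth.abundances * mask[:, :, None]
        pc_ds = add_pseudocount(masked)
        clr = clr_transform(pc_ds)
        c = clr.pseudo_count
        pseudo_counts.append(c)
        true_clr = clr_with_pseudocount(truth, c).clr_values
        eval_mask = np.ones((s, k), dtype=int)
        eval_mask[np.ix_(test_subjects, eval_timepoints)] = 0
        gaps = time_gaps(masked)
        for entry in methods:
            if callable(entry) or isinstance(entry, tuple):
                name, fn = entry if isinstance(entry, tuple) else (entry.__name__, entry)
                result = fn(clr, mask)
            elif entry in BASELINE_METHODS:
                name = entry
                result = impute_baseline(clr, mask, BaselineSpec(method=entry))
            elif entry in GAN_METHODS:
                name = entry
                variant = entry.split("_", 1)[1]
                tcfg = (training_config if training_config is not None
                        else TrainingConfig())
                tcfg = dataclasses.replace(tcfg, seed=seed * 1000 + fold)
                model = MicrobiomeGANImputer(clr, gaps=gaps, variant=variant)
                result = model.fit(tcfg).impute()
            else:
                raise MicrogenError(f"unknown method {entry!r}")
            records.append({
                "method": name,
                "fold": fold,
                "mae_clr": mae_clr(true_clr, result.clr_values, eval_mask),
                "n_eval_samples": int((eval_mask == 0).sum()),
            })
    return BenchmarkResult(per_fold=pd.DataFrame.from_records(records),
                           pseudo_counts=pseudo_counts)
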