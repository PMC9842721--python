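"""Reconstruction scoring and model-comparison statistics.

Evaluation follows the conventions of the envelope-decoding literature:
Pearson correlation between the reconstructed and actual envelope is
computed per 5 s window, averaged over windows per stimulus, then averaged
over stimuli per subject.  Paired model comparisons use a two-sided
Wilcoxon signed-rank test with Holm-Bonferroni correction over the declared
family of comparisons; reported p-values are the corrected ones.

The dependence of subject-independent performance on the number of training
subjects is summarized by fitting ``r(x) = tanh(x / a) ** b`` to
(number of subjects, median score) points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from . import nn
from .containers import SubjectScore, WindowPairSet
from .model import DecoderModel

__all__ = [
    "evaluate_decoder",
    "window_correlations",
    "validation_loss",
    "compare_models",
    "wilcoxon_signed_rank",
    "holm_correction",
    "CurveFit",
    "fit_subject_curve",
    "scores_to_frame",
]


def window_correlations(model: DecoderModel, windows: WindowPairSet, batch_size: int = 64) -> np.ndarray:
    """Per-window Pearson r between reconstruction and target envelope.

    Windows with an undefined correlation (zero-variance prediction or
    target) come back as NaN.
    """
    pred = model.predict(windows.eeg, batch_size=batch_size)
    return nn.pearson_batch(np.asarray(pred, np.float64), windows.envelope)


def validation_loss(model: DecoderModel, windows: WindowPairSet, batch_size: int = 64) -> float:
    """Mean negative Pearson r over windows (NaN windows excluded)."""
    r = window_correlations(model, windows, batch_size)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("no window had a defined correlation")
    return float(-r.mean())


def evaluate_decoder(model: DecoderModel, test_windows: WindowPairSet) -> list[SubjectScore]:
    """Score a decoder: window r -> per-stimulus mean -> per-subject mean.

    Windows whose correlation is undefined are excluded and counted in
    ``SubjectScore.n_excluded``.
    """
    r = window_correlations(model, test_windows)
    frame = pd.DataFrame(
        {
            "subject": test_windows.subject_ids,
            "stimulus": test_windows.stimulus_ids,
            "r": r,
        }
    )
    out = []
    for subject, grp in frame.groupby("subject", sort=True):
        n_excluded = int(grp["r"].isna().sum())
        per_stim = grp.dropna(subset=["r"]).groupby("stimulus")["r"].mean()
        out.append(
            SubjectScore(
                subject_id=str(subject),
                per_stimulus=per_stim.to_dict(),
                score=float(per_stim.mean()),
                n_excluded=n_excluded,
            )
        )
    return out


def scores_to_frame(scores: list[SubjectScore]) -> pd.DataFrame:
    """Long-format (subject, stimulus, r) table of per-stimulus scores."""
    rows = [
        {"subject": s.subject_id, "stimulus": stim, "r": r}
        for s in scores
        for stim, r in s.per_stimulus.items()
    ]
    return pd.DataFrame(rows, columns=["subject", "stimulus", "r"])


def _as_score_array(scores) -> np.ndarray:
    if len(scores) and isinstance(scores[0], SubjectScore):
        return np.array([s.score for s in sorted(scores, key=lambda s: s.subject_id)])
    return np.asarray(scores, dtype=np.float64)


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped (Wilcoxon's convention); if *all*
    differences are zero the test is degenerate and ``p = 1`` is returned.
    Uses the exact null distribution for n <= 25 and the normal
    approximation with continuity correction above.
    """
    a = _as_score_array(a)
    b = _as_score_array(b)
    if a.shape != b.shape:
        raise ValueError("paired score arrays must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    method = "exact" if d.size <= 25 else "approx"
    res = scipy.stats.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                               alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def holm_correction(pvalues) -> np.ndarray:
    """Holm-Bonferroni step-down corrected p-values (family-wise error)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def compare_models(
    score_sets: dict[str, object],
    comparisons: list[tuple[str, str]],
    min_subjects: int = 5,
) -> pd.DataFrame:
    """Pairwise Wilcoxon tests across a family, Holm-corrected.

    ``score_sets`` maps a model name to its per-subject scores (arrays or
    :class:`SubjectScore` lists, paired by subject).  ``comparisons`` is the
    declared family of (name_a, name_b) pairs; the correction spans exactly
    this family.  Returns a table with raw and corrected p-values.
    """
    arrays = {k: _as_score_array(v) for k, v in score_sets.items()}
    lengths = {len(v) for v in arrays.values()}
    if len(lengths) != 1:
        raise ValueError(f"score sets are not paired: lengths {sorted(lengths)}")
    (n,) = lengths
    if n < min_subjects:
        raise ValueError(f"need at least {min_subjects} paired subjects, got {n}")
    rows = []
    for name_a, name_b in comparisons:
        stat, p = wilcoxon_signed_rank(arrays[name_a], arrays[name_b])
        rows.append({"model_a": name_a, "model_b": name_b, "statistic": stat, "p_raw": p})
    frame = pd.DataFrame(rows)
    frame["p_corrected"] = holm_correction(frame["p_raw"].to_numpy())
    return frame


@dataclass
class CurveFit:
    """Fit of ``median r = tanh(x / a) ** b`` to subjects-vs-score points."""

    a: float
    b: float
    residuals: np.ndarray

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("curve parameters must be positive")

    def __call__(self, x) -> np.ndarray:
        return np.tanh(np.asarray(x, dtype=np.float64) / self.a) ** self.b


def fit_subject_curve(x, y) -> CurveFit:
    """Least-squares fit of the saturating subjects-vs-performance curve.

    Positivity of both parameters is enforced by optimizing their
    logarithms; the fit starts at ``a = median(x), b = 1``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.any(x <= 0):
        raise ValueError("subject counts must be positive")

    def f(xv, la, lb):
        return np.tanh(xv / np.exp(la)) ** np.exp(lb)

    p0 = (np.log(np.median(x)), 0.0)
    try:
        popt, _ = scipy.optimize.curve_fit(f, x, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"tanh curve fit did not converge: {err}") from err
    a, b = float(np.exp(popt[0])), float(np.exp(popt[1]))
    fit = CurveFit(a, b, residuals=y - np.tanh(x / a) ** b)
    return fit
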