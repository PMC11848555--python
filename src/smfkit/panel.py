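"""Biomarker panel derivation: attribution x fold change x t-test.

The panel is the triple intersection of (i) the top fraction of signals by
integrated-gradients contribution to the trained classifier, (ii) signals
with |log2 fold change| above a threshold (1.8 by default), and (iii)
signals with a two-sided Welch t-test p-value below alpha (0.05).  Panel
members are annotated offline against a local mass table within a ppm
tolerance, allowing for common cation adducts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FeatureMatrix
from .classify import ModelSpec, auc_delong, crossvalidate

__all__ = [
    "AttributionMatrix", "Panel", "integrated_gradients", "rank_signals",
    "fold_change", "t_tests", "select_panel", "evaluate_panel", "annotate",
    "ADDUCT_OFFSETS",
]

#: monoisotopic adduct mass offsets (Da) for positive-mode LDI of metabolites
ADDUCT_OFFSETS = {"[M+H]+": 1.007276, "[M+Na]+": 22.989218, "[M+K]+": 38.963158}


@dataclass
class AttributionMatrix:
    """Per-sample, per-signal integrated-gradients attributions."""

    values: np.ndarray  # samples x signals
    baseline: np.ndarray
    n_steps: int
    completeness_gap: np.ndarray  # per sample, |sum(IG) - (F(x) - F(b))|
    delta_f: np.ndarray = field(default_factory=lambda: np.empty(0))


def integrated_gradients(scorer, x: np.ndarray, baseline: np.ndarray | None = None,
                         n_steps: int = 300) -> AttributionMatrix:
    """Integrated gradients along the straight path from baseline to input.

    ``IG_i(x) = (x_i - b_i) * mean_s dF/dx_i( b + a_s (x - b) )`` with the
    midpoint rule ``a_s = (s + 1/2)/n_steps``; F is the scorer's class-1
    probability.  The completeness axiom (attributions summing to
    ``F(x) - F(b)``) is recorded per sample as a diagnostic.

    The scorer must expose ``decision_scores`` and ``input_gradient``
    (exact input-space gradients), as the fingerprint network does.
    """
    if not hasattr(scorer, "input_gradient"):
        raise TypeError("scorer does not expose input gradients; "
                        "integrated gradients requires a differentiable model")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, d = x.shape
    b = np.zeros(d) if baseline is None else np.asarray(baseline, dtype=float)
    if b.shape != (d,):
        raise ValueError("baseline dimension mismatch")

    alphas = (np.arange(n_steps) + 0.5) / n_steps
    attr = np.empty((n, d))
    for i in range(n):
        path = b[None, :] + alphas[:, None] * (x[i] - b)[None, :]
        grads = scorer.input_gradient(path)  # (n_steps, d)
        attr[i] = (x[i] - b) * grads.mean(axis=0)

    f_x = np.asarray(scorer.decision_scores(x), dtype=float)
    f_b = float(np.asarray(scorer.decision_scores(b[None, :]))[0])
    delta = f_x - f_b
    gap = np.abs(attr.sum(axis=1) - delta)
    return AttributionMatrix(values=attr, baseline=b, n_steps=n_steps,
                             completeness_gap=gap, delta_f=delta)


def rank_signals(attr: AttributionMatrix, signal_mz: np.ndarray,
                 top_fraction: float = 0.20) -> np.ndarray:
    """Indices of the top fraction of signals by mean |attribution|.

    Signals are ranked by mean absolute attribution across samples,
    descending; the top ``ceil(fraction * n_signals)`` are returned.  Ties
    break toward ascending m/z.
    """
    if attr.values.size == 0:
        raise ValueError("empty attribution matrix")
    contribution = np.abs(attr.values).mean(axis=0)
    n_keep = math.ceil(top_fraction * len(contribution))
    order = np.lexsort((np.asarray(signal_mz), -contribution))
    return np.sort(order[:n_keep])


def fold_change(matrix: FeatureMatrix) -> np.ndarray:
    """log2(case mean / control mean) per signal, on raw intensities.

    A zero group mean is replaced by a pseudo-intensity of half the smallest
    nonzero value observed for that signal, keeping log2FC finite; a signal
    that is zero everywhere gets log2FC 0.
    """
    case, control = _split_groups(matrix)
    mean_case = case.mean(axis=0)
    mean_ctrl = control.mean(axis=0)
    out = np.zeros(matrix.n_signals)
    for j in range(matrix.n_signals):
        mc, mh = mean_case[j], mean_ctrl[j]
        if mc == 0 and mh == 0:
            continue
        col = matrix.values[:, j]
        nonzero = col[col > 0]
        eps = nonzero.min() / 2.0
        out[j] = math.log2(max(mc, eps) / max(mh, eps))
    return out


def t_tests(matrix: FeatureMatrix) -> np.ndarray:
    """Two-sided Welch t-test p-value per signal (case vs control)."""
    case, control = _split_groups(matrix)
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need >= 2 samples per group")
    res = stats.ttest_ind(case, control, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # both groups constant and equal: no evidence against the null
    p[np.isnan(p)] = 1.0
    return p


def _split_groups(matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    if matrix.labels is None:
        raise ValueError("feature matrix has no group labels")
    labels = np.array([str(v) for v in matrix.labels])
    uniq = set(labels)
    pos = "case" if "case" in uniq else ("MMD" if "MMD" in uniq else sorted(uniq)[1])
    case = matrix.values[labels == pos]
    control = matrix.values[labels != pos]
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both groups must be non-empty")
    return case, control


@dataclass
class Panel:
    """Signals passing all three filters, with effect direction."""

    indices: np.ndarray
    signal_mz: np.ndarray
    log2fc: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray  # BH-adjusted, reported for transparency
    ig_rank: np.ndarray  # 1-based rank by contribution
    direction: list[str]  # "up" / "down" in cases

    def __len__(self) -> int:
        return len(self.indices)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "signal_mz": self.signal_mz, "log2fc": self.log2fc,
            "p_value": self.p_value, "q_value": self.q_value,
            "ig_rank": self.ig_rank, "direction": self.direction,
        }, index=pd.Index(self.indices, name="signal_index"))


def select_panel(top_ig_indices: np.ndarray, log2fc: np.ndarray,
                 p_values: np.ndarray, signal_mz: np.ndarray,
                 fc_min: float = 1.8, alpha: float = 0.05,
                 attr: AttributionMatrix | None = None) -> Panel:
    """Triple intersection of the IG, fold-change and t-test filters."""
    if len(log2fc) != len(p_values) or len(log2fc) != len(signal_mz):
        raise ValueError("filter inputs must cover the same signal set")
    ig_set = set(int(i) for i in np.asarray(top_ig_indices))
    members = [j for j in range(len(log2fc))
               if j in ig_set and abs(log2fc[j]) > fc_min and p_values[j] < alpha]
    members = np.array(sorted(members), dtype=int)

    if attr is not None and attr.values.size:
        contribution = np.abs(attr.values).mean(axis=0)
        full_rank = np.empty(len(contribution), dtype=int)
        order = np.lexsort((np.asarray(signal_mz), -contribution))
        full_rank[order] = np.arange(1, len(contribution) + 1)
        ranks = full_rank[members]
    else:
        ranks = np.zeros(len(members), dtype=int)

    q = multipletests(p_values, method="fdr_bh")[1] if len(p_values) else np.empty(0)
    return Panel(
        indices=members,
        signal_mz=np.asarray(signal_mz)[members],
        log2fc=np.asarray(log2fc)[members],
        p_value=np.asarray(p_values)[members],
        q_value=np.asarray(q)[members],
        ig_rank=ranks,
        direction=["up" if log2fc[j] > 0 else "down" for j in members],
    )


def evaluate_panel(matrix: FeatureMatrix, panel: Panel,
                   model: ModelSpec | str = "nn", k: int = 10,
                   repeats: int = 3, seed: int = 0) -> dict:
    """Cross-validated AUC of the panel plus univariate per-member AUCs.

    Single-member AUCs use the raw feature value as the score, oriented by
    the member's regulation direction.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    sub = matrix.restrict(panel.indices)
    sub.labels = matrix.labels
    rep = crossvalidate(sub, model, k=k, repeats=repeats, seed=seed)
    panel_auc, _, ci = auc_delong(rep.pooled_scores(), rep.y)

    member_aucs = []
    for pos, j in enumerate(panel.indices):
        score = matrix.values[:, j]
        if panel.direction[pos] == "down":
            score = -score
        member_aucs.append(auc_delong(score, rep.y)[0])
    return {
        "panel_auc": float(panel_auc), "panel_auc_ci": ci,
        "member_auc": [float(a) for a in member_aucs],
        "best_single_auc": float(max(member_aucs)),
        "cv_report": rep,
    }


def annotate(panel: Panel, mass_table: pd.DataFrame,
             ppm_tol: float = 150.0,
             adducts: dict[str, float] = ADDUCT_OFFSETS) -> pd.DataFrame:
    """Match panel m/z values to a local mass table within a ppm tolerance.

    ``mass_table`` needs columns ``name`` and ``monoisotopic_mass`` (neutral,
    Da).  Each observed m/z is compared against mass + adduct offset for
    every adduct; all matches within ``ppm_tol`` are listed, nearest first.
    """
    if mass_table is None or len(mass_table) == 0:
        import warnings
        warnings.warn("empty mass table: annotation skipped")
        return pd.DataFrame(columns=["signal_mz", "name", "adduct",
                                     "theoretical_mz", "ppm_error"])
    rows = []
    for mz in panel.signal_mz:
        for _, entry in mass_table.iterrows():
            for adduct, offset in adducts.items():
                theo = float(entry["monoisotopic_mass"]) + offset
                ppm = abs(mz - theo) / theo * 1e6
                if ppm <= ppm_tol:
                    rows.append((float(mz), str(entry["name"]), adduct, theo, ppm))
    out = pd.DataFrame(rows, columns=["signal_mz", "name", "adduct",
                                      "theoretical_mz", "ppm_error"])
    return out.sort_values(["signal_mz", "ppm_error"]).reset_index(drop=True)
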