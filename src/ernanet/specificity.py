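"""Tissue-specificity index (TSI) and tissue-specific feature calling.

For a feature measured across N tissues, expression is max-normalized
(x_i = expr_i / max_j expr_j) and

    TSI = sum_i (1 - x_i) / (N - 1),

the standard tau index: 0 for uniform expression, 1 for single-tissue
expression. A feature is tissue-specific in a breed when TSI > 0.8
(strictly) in both biological replicates and both replicates agree on the
maximally expressed tissue; that tissue is the assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TSI_THRESHOLD = 0.8


@dataclass
class TsiResult:
    feature_id: str
    breed: str
    tsi_by_replicate: dict[int, float | None]
    argmax_by_replicate: dict[int, str | None]
    is_specific: bool
    assigned_tissue: str | None


def tsi(expression_vector: np.ndarray | list[float]) -> float | None:
    """Tau-style tissue-specificity index of a per-tissue expression vector.

    Returns None for an all-zero vector (undefined).
    """
    x = np.asarray(expression_vector, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("expression must be non-negative")
    m = x.max()
    if m == 0:
        return None
    xn = x / m
    return float((1.0 - xn).sum() / (len(x) - 1))


def call_tissue_specific(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    breed: str,
    threshold: float = TSI_THRESHOLD,
) -> list[TsiResult]:
    """Per-breed tissue-specific calls from a features x samples matrix.

    TSI is computed separately for replicate 1 and replicate 2 over that
    breed's tissues. ``samples`` maps columns to (breed, tissue, replicate);
    the two replicates must cover the same tissue set.
    """
    sel = samples[samples["breed"] == breed]
    reps = sorted(sel["replicate"].unique())
    tissue_sets = {
        r: frozenset(sel[sel["replicate"] == r]["tissue"]) for r in reps
    }
    if len(set(tissue_sets.values())) != 1:
        raise ValueError(f"replicate tissue sets differ for breed {breed}: {tissue_sets}")
    tissues = sorted(tissue_sets[reps[0]])
    cols = {
        r: [
            sel[(sel["replicate"] == r) & (sel["tissue"] == t)]["sample"].iloc[0]
            for t in tissues
        ]
        for r in reps
    }
    results = []
    for fid, row in expression.iterrows():
        tsis: dict[int, float | None] = {}
        argmaxes: dict[int, str | None] = {}
        for r in reps:
            vec = row[cols[r]].to_numpy(dtype=float)
            t = tsi(vec)
            tsis[r] = t
            argmaxes[r] = tissues[int(np.argmax(vec))] if t is not None else None
        ok = (
            all(t is not None and t > threshold for t in tsis.values())
            and len({a for a in argmaxes.values()}) == 1
            and next(iter(argmaxes.values())) is not None
        )
        results.append(
            TsiResult(
                feature_id=str(fid),
                breed=breed,
                tsi_by_replicate=tsis,
                argmax_by_replicate=argmaxes,
                is_specific=ok,
                assigned_tissue=argmaxes[reps[0]] if ok else None,
            )
        )
    return results


def detectable_genes(
    expression: pd.DataFrame, samples: pd.DataFrame, breed: str, tissue: str,
    min_mean_tpm: float = 1.0,
) -> set[str]:
    """Genes with mean TPM >= 1 across the tissue's replicates (per breed)."""
    cols = samples[(samples["breed"] == breed) & (samples["tissue"] == tissue)]["sample"]
    if len(cols) == 0:
        return set()
    means = expression[list(cols)].mean(axis=1)
    return set(means[means >= min_mean_tpm].index.astype(str))


def tsi_results_to_frame(results: list[TsiResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        reps = sorted(r.tsi_by_replicate)
        rows.append(
            {
                "feature": r.feature_id,
                "breed": r.breed,
                **{f"rep{i}_tsi": r.tsi_by_replicate[i] for i in reps},
                "tissue": r.assigned_tissue,
                "is_specific": r.is_specific,
            }
        )
    return pd.DataFrame(rows)
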