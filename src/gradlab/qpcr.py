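"""Relative gene expression by the delta-delta-CT (comparative CT) method.

CT is the qPCR cycle at which amplification crosses threshold; one fewer
cycle means twice the starting template.  Expression of a target gene is
normalised to a reference gene (GAPDH by default) within each condition,

    dCT(condition, gene) = mean CT(gene) - mean CT(reference),

and the fold change of a treated condition relative to control is

    fold = 2 ** -(dCT_treated - dCT_control).

Replicate CT values are averaged before differencing.  Amplification
efficiency is assumed to be exactly 2 per cycle (the conventional method);
no efficiency correction is applied.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import DataError

REFERENCE_GENE = "GAPDH"

_COLUMNS = ("condition", "gene", "replicate", "ct")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"CT table missing columns: {', '.join(missing)}")
    bad = table[(table["ct"] <= 0) | (table["ct"] >= 45)]
    if not bad.empty:
        raise DataError(
            f"CT values outside (0, 45) for rows {bad.index.tolist()[:5]}"
        )
    return table


def _mean_ct(table: pd.DataFrame, condition: str, gene: str) -> float:
    rows = table[(table["condition"] == condition) & (table["gene"] == gene)]
    if rows.empty:
        raise DataError(f"no CT rows for gene {gene!r} under condition {condition!r}")
    return float(rows["ct"].mean())


def delta_ct(
    table: pd.DataFrame, condition: str, gene: str, reference: str = REFERENCE_GENE
) -> float:
    """Reference-normalised CT: mean CT(gene) - mean CT(reference)."""
    _validate(table)
    return _mean_ct(table, condition, gene) - _mean_ct(table, condition, reference)


def fold_change(
    table: pd.DataFrame,
    treated: str,
    control: str,
    gene: str,
    reference: str = REFERENCE_GENE,
) -> float:
    """Fold change of `gene` in `treated` relative to `control`: 2**-ddCT."""
    ddct = delta_ct(table, treated, gene, reference) - delta_ct(
        table, control, gene, reference
    )
    return 2.0 ** (-ddct)


def expression_matrix(
    table: pd.DataFrame,
    stimuli: list[str],
    receptors: list[str],
    control: str = "C",
    reference: str = REFERENCE_GENE,
) -> pd.DataFrame:
    """Fold-change matrix (stimuli × receptors) relative to the control condition.

    Every requested (stimulus, receptor) pair must be present in the table;
    missing pairs are reported together in the error.
    """
    _validate(table)
    present = set(zip(table["condition"], table["gene"]))
    needed = [
        (cond, gene)
        for cond in [control, *stimuli]
        for gene in [reference, *receptors]
    ]
    gaps = [pair for pair in needed if pair not in present]
    if gaps:
        raise DataError(f"CT table lacks (condition, gene) pairs: {gaps}")
    data = {
        receptor: [fold_change(table, stim, control, receptor, reference) for stim in stimuli]
        for receptor in receptors
    }
    return pd.DataFrame(data, index=pd.Index(stimuli, name="stimulus"))
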