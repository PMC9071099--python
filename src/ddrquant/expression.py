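"""Relative gene expression by the comparative-Ct (2^-ddCt) method.

Per sample: dCt = target Ct - housekeeping Ct (GAPDH by default); ddCt is
taken against a reference sample, and fold change = 2^-ddCt, so the reference
sample's fold is exactly 1.  Technical-replicate Ct values are averaged
before dCt; undetected wells propagate as flagged missing values, never as an
imputed Ct ceiling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["delta_delta_ct"]


def delta_delta_ct(
    ct_table: pd.DataFrame,
    reference_sample: str,
    housekeeping_gene: str = "GAPDH",
    sample_col: str = "sample",
    gene_col: str = "gene",
    ct_col: str = "ct",
) -> pd.DataFrame:
    """Fold changes relative to ``reference_sample``, normalised to the
    housekeeping gene.

    Parameters
    ----------
    ct_table : DataFrame
        Long table with one row per well: sample id, gene id, Ct value.
        Technical replicates (repeated sample x gene rows) are averaged.
        Undetected wells are encoded as NaN Ct.
    reference_sample : str
        Sample whose fold change defines 1 (e.g. the 2D monolayer culture).
    housekeeping_gene : str
        Stable normaliser gene, default GAPDH.

    Returns
    -------
    DataFrame with columns sample, gene, delta_ct, delta_delta_ct,
    fold_change, undetected (flag).  Target genes only (the housekeeping
    gene itself is consumed by the normalisation).

    Raises
    ------
    ConfigurationError
        If the reference sample or a sample's housekeeping Ct is absent.
    """
    df = ct_table[[sample_col, gene_col, ct_col]].copy()
    df.columns = ["sample", "gene", "ct"]
    if np.nanmin(df["ct"].to_numpy(dtype=float)) <= 0:
        raise ValueError("finite Ct values must be positive cycle counts")
    mean_ct = df.groupby(["sample", "gene"], sort=False)["ct"].mean().reset_index()

    hk = mean_ct[mean_ct["gene"] == housekeeping_gene].set_index("sample")["ct"]
    targets = mean_ct[mean_ct["gene"] != housekeeping_gene].copy()
    if targets.empty:
        raise ConfigurationError("no target genes besides the housekeeping gene")
    missing_hk = set(targets["sample"]) - set(hk.index)
    if missing_hk:
        raise ConfigurationError(
            f"samples lack a housekeeping ({housekeeping_gene}) Ct: {sorted(missing_hk)}"
        )
    if reference_sample not in set(targets["sample"]):
        raise ConfigurationError(f"reference sample {reference_sample!r} not in the table")

    targets["delta_ct"] = targets["ct"] - targets["sample"].map(hk).to_numpy()
    ref = targets[targets["sample"] == reference_sample].set_index("gene")["delta_ct"]
    targets["delta_delta_ct"] = targets["delta_ct"] - targets["gene"].map(ref).to_numpy()
    targets["fold_change"] = 2.0 ** (-targets["delta_delta_ct"])
    targets["undetected"] = ~np.isfinite(targets["fold_change"])
    # the reference sample's fold is 1 by identity; pin it exactly
    is_ref = (targets["sample"] == reference_sample) & np.isfinite(targets["delta_ct"])
    targets.loc[is_ref, "fold_change"] = 1.0
    return targets[
        ["sample", "gene", "delta_ct", "delta_delta_ct", "fold_change", "undetected"]
    ].reset_index(drop=True)
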