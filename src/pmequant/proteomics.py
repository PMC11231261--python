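"""MVB-fraction proteomics post-processing.

Abundance filtering by peptide-spectrum-match (PSM) count and log2
fold-change enrichment of the MVB fraction over the whole-egg lysate
control. Proteins with PSM < 10 are disregarded (10 itself is kept);
a protein is MVB-enriched when log2FC strictly exceeds 1.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["protein_id", "psm", "intensity_mvb", "intensity_lysate"]


def read_protein_table(path: str | Path) -> pd.DataFrame:
    """Read the TSV protein table (protein_id, unique_peptides, psm,
    intensity_mvb, intensity_lysate)."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"protein table missing columns {missing}")
    return frame


def filter_low_abundance(rows: pd.DataFrame, min_psm: int = 10) -> pd.DataFrame:
    """Drop low-abundance proteins: PSM < min_psm removed (strict <)."""
    if not np.issubdtype(rows["psm"].dtype, np.integer):
        if not np.all(rows["psm"] == rows["psm"].astype(int)):
            raise ValueError("PSM counts must be integers")
    return rows[rows["psm"] >= min_psm].reset_index(drop=True)


def enrich_log2fc(rows: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Compute log2FC = log2((I_mvb + ε)/(I_lysate + ε)) and the enriched flag.

    ε defaults to half the smallest nonzero intensity in the table,
    which avoids infinities while preserving ranks. A protein with both
    intensities zero is flagged not-quantified (log2FC = NaN).
    """
    rows = rows.copy()
    i_mvb = rows["intensity_mvb"].to_numpy(dtype=float)
    i_lys = rows["intensity_lysate"].to_numpy(dtype=float)
    if np.any(i_mvb < 0) or np.any(i_lys < 0):
        raise ValueError("intensities must be >= 0")
    if pseudocount is None:
        nonzero = np.concatenate([i_mvb[i_mvb > 0], i_lys[i_lys > 0]])
        pseudocount = float(nonzero.min() / 2) if nonzero.size else 1.0
    quantified = ~((i_mvb == 0) & (i_lys == 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2((i_mvb + pseudocount) / (i_lys + pseudocount))
    log2fc = np.where(quantified, log2fc, np.nan)
    rows["log2fc"] = log2fc
    rows["quantified"] = quantified
    rows["enriched"] = quantified & (log2fc > 1.0)
    return rows


def mvb_enrichment(
    rows: pd.DataFrame, min_psm: int = 10, pseudocount: float | None = None
) -> pd.DataFrame:
    """Full post-processing: abundance filter then enrichment listing."""
    return enrich_log2fc(filter_low_abundance(rows, min_psm), pseudocount)


def write_protein_table(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, sep="\t", index=False)
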