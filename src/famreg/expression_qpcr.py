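"""Relative-expression arithmetic (2^-ddCt) and log2 FPKM transforms."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import ExpressionMatrix, FormatError


@dataclass(frozen=True)
class CtRow:
    sample: str
    gene: str
    cts: tuple[float, ...]

    def __post_init__(self):
        if not self.cts:
            raise ValueError(f"{self.sample}/{self.gene}: no Ct replicates")
        if any(ct <= 0 for ct in self.cts):
            raise ValueError(f"{self.sample}/{self.gene}: Ct values must be > 0")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.cts))


def read_ct_table(path) -> list[CtRow]:
    """Read a Ct TSV: sample, gene, then one column per replicate Ct."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "gene"} <= set(df.columns):
        raise FormatError("Ct table must have columns sample, gene")
    rep_cols = [c for c in df.columns if c not in ("sample", "gene")]
    rows = []
    for r in df.itertuples():
        cts = tuple(
            float(getattr(r, c)) for c in rep_cols if pd.notna(getattr(r, c))
        )
        rows.append(CtRow(sample=str(r.sample), gene=str(r.gene), cts=cts))
    return rows


def ddct(
    table: list[CtRow],
    reference_gene: str,
    calibrator_sample: str,
) -> dict[tuple[str, str], float]:
    """2^-ddCt fold changes per (sample, gene).

    Replicate Cts are averaged on the Ct scale; dCt = mean Ct(gene) -
    mean Ct(reference) within each sample; ddCt subtracts the calibrator
    sample's dCt. The reference gene must be measured in every sample.
    """
    mean_ct: dict[tuple[str, str], float] = {}
    for row in table:
        key = (row.sample, row.gene)
        if key in mean_ct:  # merge repeated rows as extra replicates
            mean_ct[key] = (mean_ct[key] + row.mean_ct) / 2.0
        else:
            mean_ct[key] = row.mean_ct
    samples = sorted({s for s, _ in mean_ct})
    genes = sorted({g for _, g in mean_ct if g != reference_gene})
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")
    for sample in samples:
        if (sample, reference_gene) not in mean_ct:
            raise ValueError(
                f"reference gene {reference_gene!r} not measured in sample {sample!r}"
            )
    dct = {
        (s, g): mean_ct[(s, g)] - mean_ct[(s, reference_gene)]
        for s in samples
        for g in genes
        if (s, g) in mean_ct
    }
    folds = {}
    for (s, g), value in dct.items():
        cal_key = (calibrator_sample, g)
        if cal_key not in dct:
            raise ValueError(
                f"gene {g!r} not measured in calibrator {calibrator_sample!r}"
            )
        ddct_value = value - dct[cal_key]
        folds[(s, g)] = float(2.0 ** (-ddct_value))
    return folds


def log2_matrix(expr: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(FPKM + pseudocount), heatmap-ready."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = expr.data.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative expression values")
    return pd.DataFrame(
        np.log2(values + pseudocount),
        index=expr.data.index,
        columns=expr.data.columns,
    )


def fold_changes_to_tsv(folds: dict[tuple[str, str], float], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgene\tfold_change\n")
        for (sample, gene), fold in sorted(folds.items()):
            fh.write(f"{sample}\t{gene}\t{fold:.6g}\n")
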