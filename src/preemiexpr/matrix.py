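"""Core expression containers: raw count and normalized matrices.

Counts are stored genes x subjects, matching the layout of the TSV and
MatrixMarket interchange formats used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class CountMatrix:
    """Raw integer read counts, genes x subjects.

    Parameters
    ----------
    counts
        DataFrame with unique gene identifiers as the index and unique
        subject identifiers as columns; all values non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate subject identifiers")
        values = self.counts.to_numpy()
        if values.size and ((values < 0).any() or not np.allclose(values, np.round(values))):
            raise ValueError("counts must be non-negative integers")
        # canonical form: axis labels carry no names regardless of source
        self.counts.index.name = None
        self.counts.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    # ------------------------------------------------------------------ IO
    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_mtx(self, prefix: str | Path) -> None:
        """Write MatrixMarket ``<prefix>.mtx`` plus row/column name sidecars."""
        prefix = Path(prefix)
        sparse = scipy.sparse.csr_matrix(self.counts.to_numpy())
        scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), sparse)
        prefix.with_suffix(".rownames.txt").write_text("\n".join(self.gene_ids) + "\n")
        prefix.with_suffix(".colnames.txt").write_text("\n".join(self.subject_ids) + "\n")

    @classmethod
    def from_mtx(cls, prefix: str | Path) -> "CountMatrix":
        prefix = Path(prefix)
        mat = scipy.io.mmread(str(prefix.with_suffix(".mtx"))).toarray()
        genes = prefix.with_suffix(".rownames.txt").read_text().splitlines()
        subjects = prefix.with_suffix(".colnames.txt").read_text().splitlines()
        df = pd.DataFrame(np.asarray(mat, dtype=np.int64), index=genes, columns=subjects)
        return cls(df)

    def subset(self, genes=None, subjects=None) -> "CountMatrix":
        df = self.counts
        if genes is not None:
            df = df.loc[list(genes)]
        if subjects is not None:
            df = df[list(subjects)]
        return CountMatrix(df.copy())


@dataclass
class NormalizedMatrix:
    """log2 upper-quartile-normalized expression with provenance.

    ``log2_values`` holds log2(raw / f_s + 1); the pre-log normalized values
    are recovered lazily as ``2**log2_values - 1`` rather than stored twice.
    """

    log2_values: pd.DataFrame
    norm_factors: pd.Series
    conditional_uq: pd.Series
    filter_report: dict = field(default_factory=dict)

    @property
    def pre_log(self) -> pd.DataFrame:
        """Normalized (raw / f_s) values before the +1 / log2 transform."""
        return np.exp2(self.log2_values) - 1.0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.log2_values.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.log2_values.columns)

    def subset(self, genes=None, subjects=None) -> "NormalizedMatrix":
        df = self.log2_values
        if genes is not None:
            df = df.loc[list(genes)]
        if subjects is not None:
            df = df[list(subjects)]
        return NormalizedMatrix(
            df.copy(),
            self.norm_factors.loc[df.columns].copy(),
            self.conditional_uq.loc[df.columns].copy(),
            dict(self.filter_report),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.log2_values.to_csv(path, sep="\t", index_label="gene_id")
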