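"""Expression-matrix container shared by all pipeline stages.

The matrix is genes x samples. Values are either linear-scale (TPM-like,
non-negative) or log2-scale; the ``scale`` flag records which, because the
specificity filters are defined on the linear scale while reference
microarray compendia are conventionally stored in log2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LINEAR = "linear"
LOG2 = "log2"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with optional per-sample labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.
    sample_labels
        Optional mapping sample -> label (cell type, tumor/normal,
        phenotype class).
    scale
        ``"linear"`` (non-negative) or ``"log2"``.
    """

    values: pd.DataFrame
    sample_labels: dict[str, str] = field(default_factory=dict)
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene IDs in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in expression matrix")
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == LINEAR and (self.values.to_numpy() < 0).any():
            raise ValueError("linear-scale expression must be non-negative")
        unknown = set(self.sample_labels) - set(self.values.columns)
        if unknown:
            raise ValueError(f"labels refer to unknown samples: {sorted(unknown)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale view (exponentiating log2 values)."""
        if self.scale == LINEAR:
            return self
        return ExpressionMatrix(
            np.exp2(self.values), dict(self.sample_labels), LINEAR
        )

    def to_log2(self, pseudo: float = 0.0) -> "ExpressionMatrix":
        if self.scale == LOG2:
            return self
        return ExpressionMatrix(
            np.log2(self.values + pseudo) if pseudo else np.log2(self.values),
            dict(self.sample_labels),
            LOG2,
        )

    def samples_with_label(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_labels.get(s) == label]

    def labels_by_type(self) -> dict[str, list[str]]:
        """Group sample IDs by their label, preserving column order."""
        out: dict[str, list[str]] = {}
        for s in self.sample_ids:
            lab = self.sample_labels.get(s)
            if lab is not None:
                out.setdefault(lab, []).append(s)
        return out

    # ---- I/O -----------------------------------------------------------

    def write_tsv(self, path, labels_path=None) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        if labels_path is not None:
            pd.Series(self.sample_labels, name="label").rename_axis(
                "sample_id"
            ).to_csv(labels_path, sep="\t")

    @classmethod
    def read_tsv(cls, path, labels_path=None, scale: str = LINEAR) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        labels: dict[str, str] = {}
        if labels_path is not None:
            lab = pd.read_csv(labels_path, sep="\t", index_col=0)
            labels = lab.iloc[:, 0].astype(str).to_dict()
        return cls(values, labels, scale)
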