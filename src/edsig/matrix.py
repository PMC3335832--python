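"""Core expression-matrix container.

A probe-level expression matrix together with its Illumina-style detection
p-values, probe annotations (gene symbols), and per-sample annotations
(disease group, sex, subject id). Values may be on the raw intensity scale or
on the log2 scale; the ``scale`` flag records which, and downstream
operations check it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

INTENSITY = "intensity"
LOG2 = "log2"

#: sample-annotation columns every matrix carries (missing ones are added empty)
SAMPLE_COLUMNS = ("group", "sex", "subject_id")


@dataclass
class ExpressionMatrix:
    """Probes x samples expression data with detection p-values.

    Parameters
    ----------
    values
        probes x samples numeric frame (intensities or log2 values).
    detection_p
        probes x samples detection p-values in [0, 1]; same index/columns
        as ``values``.
    probe_annotations
        probe id -> gene symbol; probes without a symbol are NaN.
    sample_annotations
        sample id -> at least a ``group`` column; ``sex`` and
        ``subject_id`` are filled if absent.
    scale
        ``"intensity"`` (strictly positive values) or ``"log2"``.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame
    probe_annotations: pd.Series
    sample_annotations: pd.DataFrame
    scale: str = INTENSITY

    def __post_init__(self) -> None:
        if self.scale not in (INTENSITY, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.shape != self.detection_p.shape:
            raise ValueError(
                "values and detection_p dimensions differ: "
                f"{self.values.shape} vs {self.detection_p.shape}"
            )
        if not self.values.index.equals(self.detection_p.index):
            raise ValueError("values and detection_p probe ids differ")
        if not self.values.columns.equals(self.detection_p.columns):
            raise ValueError("values and detection_p sample ids differ")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()][:3]
            raise ValueError(f"duplicate probe ids, e.g. {list(dups)}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.scale == INTENSITY:
            arr = self.values.to_numpy()
            if np.nanmin(arr) < 0:
                raise ValueError("negative values on intensity scale")
        self.probe_annotations = self.probe_annotations.reindex(self.values.index)
        self.sample_annotations = self.sample_annotations.reindex(self.values.columns)
        for col in SAMPLE_COLUMNS:
            if col not in self.sample_annotations.columns:
                self.sample_annotations[col] = pd.NA

    # -- basic accessors ---------------------------------------------------

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> pd.Series:
        """Group label per sample."""
        return self.sample_annotations["group"]

    def group_labels(self) -> list[str]:
        """Distinct group labels in sample order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.groups():
            if g not in seen:
                seen[g] = None
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        mask = self.groups() == group
        return list(self.samples[mask.to_numpy()])

    def gene_symbol(self, probe: str) -> str | None:
        sym = self.probe_annotations.get(probe)
        if sym is None or (isinstance(sym, float) and np.isnan(sym)):
            return None
        return str(sym)

    # -- derived matrices --------------------------------------------------

    def subset_probes(self, probes: Sequence[str] | Iterable[str]) -> "ExpressionMatrix":
        probes = list(probes)
        missing = set(probes) - set(self.probes)
        if missing:
            raise KeyError(f"probes not in matrix: {sorted(missing)[:5]}")
        return replace(
            self,
            values=self.values.loc[probes],
            detection_p=self.detection_p.loc[probes],
            probe_annotations=self.probe_annotations.loc[probes],
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = list(samples)
        return replace(
            self,
            values=self.values[samples],
            detection_p=self.detection_p[samples],
            sample_annotations=self.sample_annotations.loc[samples],
        )

    def with_values(self, values: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        """Return a copy holding ``values`` (same shape/labels) on ``scale``."""
        return replace(self, values=values, scale=scale)
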