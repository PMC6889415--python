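"""Feature x sample intensity matrices with metadata and missingness.

The :class:`OmicsMatrix` is the common currency of the statistics pipeline:
a features-by-samples table of intensities (linear scale on input, log2
normalized after :func:`aktredox.stats.normalize`), a congruent missingness
mask, and per-sample metadata (treatment, time, replicate, channel).
Missing cells are stored as NaN; the mask is True where a value was observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "treatment", "time", "replicate", "channel"]


@dataclass
class OmicsMatrix:
    """Intensity matrix plus sample metadata.

    Parameters
    ----------
    values
        DataFrame of intensities, features in rows (index = feature ids),
        samples in columns. NaN marks a missing cell.
    samples
        DataFrame with one row per sample and columns
        ``sample_id, treatment, time, replicate, channel``; ``sample_id``
        must match ``values.columns``.
    scale
        ``"linear"`` for raw positive intensities, ``"log2-normalized"``
        after normalization.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "linear"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2-normalized"):
            raise ValueError(f"unknown scale {self.scale!r}")
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"samples table lacks columns {missing_cols}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in matrix columns")
        sample_ids = list(self.samples["sample_id"])
        if sorted(sample_ids) != sorted(self.values.columns):
            raise ValueError("samples table does not cover matrix columns")
        # keep metadata row order aligned with the matrix columns
        self.samples = (
            self.samples.set_index("sample_id").loc[list(self.values.columns)].reset_index()
        )
        if self.scale == "linear":
            observed = self.values.to_numpy(dtype=float)
            bad = (observed <= 0) & ~np.isnan(observed)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    "non-positive intensity at feature "
                    f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
                )

    # -- basic views -----------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed-mask, congruent with ``values``."""
        return self.values.notna()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> pd.core.groupby.DataFrameGroupBy:
        """Group the sample table by (treatment, time)."""
        return self.samples.groupby(["treatment", "time"], sort=False)

    def sample_ids_for(self, treatment: str, time: str) -> list[str]:
        sel = (self.samples["treatment"] == treatment) & (self.samples["time"] == time)
        return list(self.samples.loc[sel, "sample_id"])

    def copy(self) -> "OmicsMatrix":
        return replace(
            self,
            values=self.values.copy(),
            samples=self.samples.copy(),
            flags=dict(self.flags),
        )

    # -- I/O -------------------------------------------------------------

    def write(self, matrix_path: str | Path, samples_path: str | Path | None = None) -> None:
        """Write the matrix as TSV (first column = feature id) and the
        samples sidecar as TSV."""
        matrix_path = Path(matrix_path)
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(matrix_path, sep="\t", float_format="%.10g")
        if samples_path is None:
            samples_path = matrix_path.with_name("samples.tsv")
        self.samples[SAMPLE_COLUMNS].to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read(
        cls,
        matrix_path: str | Path,
        samples_path: str | Path | None = None,
        scale: str = "linear",
    ) -> "OmicsMatrix":
        matrix_path = Path(matrix_path)
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        if samples_path is None:
            samples_path = matrix_path.with_name("samples.tsv")
        samples = pd.read_csv(samples_path, sep="\t", dtype={"time": str, "treatment": str})
        samples["sample_id"] = samples["sample_id"].astype(str)
        return cls(values=values, samples=samples, scale=scale)
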