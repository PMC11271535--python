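"""Features x samples log2-intensity container used across the pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class QuantMatrix:
    """Log2 intensities of features (peptides/proteins/sites) per sample.

    ``values`` is a DataFrame indexed by feature id with one column per
    sample; missingness is NaN, never zero.  ``sample_groups`` maps each
    sample to its group label; ``feature_meta`` carries per-feature
    annotations (gene, modification, housekeeping flag, ...).
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.sample_groups = pd.Series(self.sample_groups)
        missing = set(self.values.columns) - set(self.sample_groups.index)
        if missing:
            raise ValidationError(
                f"samples without group labels: {sorted(missing)[:5]}"
            )
        self.sample_groups = self.sample_groups.loc[list(self.values.columns)]
        if self.feature_meta.empty:
            self.feature_meta = pd.DataFrame(index=self.values.index)
        else:
            self.feature_meta = self.feature_meta.reindex(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, group: str) -> list[str]:
        return list(self.sample_groups.index[self.sample_groups == group])

    def observed_fraction(self) -> pd.Series:
        """Per-feature fraction of samples with an observed value."""
        return self.values.notna().mean(axis=1)

    def subset_samples(self, samples: list[str]) -> "QuantMatrix":
        return QuantMatrix(
            self.values[samples],
            self.sample_groups.loc[samples],
            self.feature_meta,
        )

    # -- I/O -----------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write values as TSV plus a JSON sidecar with the metadata."""
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="feature_id")
        sidecar = {
            "sample_groups": self.sample_groups.to_dict(),
            "feature_meta": json.loads(
                self.feature_meta.to_json(orient="index")
            ),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QuantMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col="feature_id")
        sidecar = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text()
        )
        meta = pd.DataFrame.from_dict(sidecar["feature_meta"], orient="index")
        meta.index = meta.index.astype(values.index.dtype, copy=False)
        return cls(
            values,
            pd.Series(sidecar["sample_groups"]),
            meta.reindex(values.index),
        )
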