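"""Tabular containers shared across the pipeline.

A :class:`FeatureTable` is the aligned injections × features intensity
matrix produced by untargeted LC-MS preprocessing, together with the
acquisition metadata (injection order, batch, QC/subject role) that the
drift-correction stage needs.  Missing (below-detection) entries are
encoded as NaN.  A :class:`ConcentrationTable` holds absolute metabolite
concentrations per subject from the targeted assay.

Both round-trip through plain TSV so every intermediate of the pipeline
is inspectable with standard tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every sample sheet carries, in canonical order
METADATA_COLUMNS = [
    "sample_id",
    "role",
    "group",
    "cohort",
    "subtype",
    "response",
    "injection_order",
    "batch",
]


@dataclass
class FeatureTable:
    """Injections × features intensity matrix with acquisition metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample_id, one column per feature id.
        NaN marks a below-detection (missing) measurement.
    metadata
        DataFrame indexed by sample_id with ``METADATA_COLUMNS``.
        ``role`` is ``subject`` or ``qc``; ``group`` is ``case``,
        ``control`` or ``NA``; ``injection_order`` is 1-based and unique
        within a batch.
    planted_features
        Feature ids carrying a simulated case/control effect, when the
        table came from the synthetic generator.  Empty for real data.
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame
    planted_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        if not self.intensities.index.equals(self.metadata.index):
            raise ValueError("intensity matrix and metadata index mismatch")
        vals = self.intensities.to_numpy()
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative where present")
        for batch, sub in self.metadata.groupby("batch"):
            if sub["injection_order"].duplicated().any():
                raise ValueError(f"injection_order not unique within batch {batch!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def subjects(self) -> "FeatureTable":
        """Sub-table of subject (non-QC) injections."""
        mask = self.metadata["role"] == "subject"
        return FeatureTable(
            self.intensities.loc[mask],
            self.metadata.loc[mask],
            list(self.planted_features),
        )

    def qcs(self) -> "FeatureTable":
        """Sub-table of pooled-QC injections."""
        mask = self.metadata["role"] == "qc"
        return FeatureTable(
            self.intensities.loc[mask],
            self.metadata.loc[mask],
            list(self.planted_features),
        )

    def labels(self) -> np.ndarray:
        """Class labels (+1 case, −1 control) for subject rows, in row order."""
        groups = self.metadata.loc[self.metadata["role"] == "subject", "group"]
        if not set(groups) <= {"case", "control"}:
            raise ValueError("subject rows must be labelled case/control")
        return np.where(groups.to_numpy() == "case", 1, -1)

    def write(self, intensities_path, metadata_path) -> None:
        self.intensities.to_csv(intensities_path, sep="\t", index_label="sample_id")
        self.metadata.to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def read(cls, intensities_path, metadata_path) -> "FeatureTable":
        intens = pd.read_csv(intensities_path, sep="\t", index_col="sample_id")
        meta = pd.read_csv(metadata_path, sep="\t")
        missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
        if missing:
            raise SchemaError(f"metadata missing column(s): {', '.join(missing)}")
        meta = meta.set_index("sample_id", drop=False)
        meta.index.name = None
        meta = meta.loc[intens.index]
        return cls(intens, meta)


class SchemaError(ValueError):
    """A required column is absent from an input table."""


@dataclass
class ConcentrationTable:
    """Absolute concentrations (ng/mL) per subject × analyte.

    ``concentrations`` is indexed by sample_id with one column per
    analyte; ``metadata`` carries group/subtype/response labels.
    ``below_lloq`` (same shape, boolean) flags cells quantified below
    the curve's LLOQ — retained numerically, never censored.
    """

    concentrations: pd.DataFrame
    metadata: pd.DataFrame
    below_lloq: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.concentrations.index.equals(self.metadata.index):
            raise ValueError("concentration matrix and metadata index mismatch")
        if self.below_lloq is None:
            self.below_lloq = pd.DataFrame(
                False,
                index=self.concentrations.index,
                columns=self.concentrations.columns,
            )

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations.columns)

    def write(self, conc_path, metadata_path) -> None:
        out = self.concentrations.copy()
        self.metadata.to_csv(metadata_path, sep="\t", index=False)
        out.to_csv(conc_path, sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, conc_path, metadata_path) -> "ConcentrationTable":
        conc = pd.read_csv(conc_path, sep="\t", index_col="sample_id")
        meta = pd.read_csv(metadata_path, sep="\t")
        if "sample_id" not in meta.columns:
            raise SchemaError("metadata missing column(s): sample_id")
        meta = meta.set_index("sample_id", drop=False)
        meta.index.name = None
        meta = meta.loc[conc.index]
        return cls(conc, meta)
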