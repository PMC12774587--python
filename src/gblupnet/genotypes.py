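"""In-memory container for SNP dosage matrices with marker/individual metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

@dataclass
class GenotypeMatrix:
    """Individuals x markers table of 0/1/2 reference-allele dosages.

    Attributes
    ----------
    dosages : (n, m) integer array with values in {0, 1, 2}; no missingness.
    marker_ids : length-m marker names.
    chromosomes : length-m chromosome labels (strings; "X"/"Y" mark sex
        chromosomes for QC).
    individual_ids : length-n identifiers.
    individuals : optional per-individual metadata (birth_year, line, ...),
        indexed like ``individual_ids``.
    """

    dosages: np.ndarray
    marker_ids: list[str] = field(default=None)
    chromosomes: np.ndarray = field(default=None)
    individual_ids: list[str] = field(default=None)
    individuals: pd.DataFrame | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x markers array")
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            raise ValueError("genotype dosages must be coded 0/1/2 with no missing values")
        n, m = self.dosages.shape
        if self.marker_ids is None:
            self.marker_ids = [f"snp{k + 1}" for k in range(m)]
        if self.chromosomes is None:
            self.chromosomes = np.array(["1"] * m, dtype=object)
        else:
            self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        if self.individual_ids is None:
            self.individual_ids = [f"id{i + 1}" for i in range(n)]
        if len(self.marker_ids) != m or len(self.chromosomes) != m:
            raise ValueError("marker metadata length does not match marker count")
        if len(self.individual_ids) != n:
            raise ValueError("individual metadata length does not match individual count")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            marker_ids=[self.marker_ids[k] for k in keep],
            chromosomes=self.chromosomes[keep],
            individual_ids=list(self.individual_ids),
            individuals=self.individuals,
        )

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        ids = [self.individual_ids[i] for i in idx]
        meta = self.individuals.iloc[idx] if self.individuals is not None else None
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            marker_ids=list(self.marker_ids),
            chromosomes=self.chromosomes,
            individual_ids=ids,
            individuals=meta,
        )

    def is_sex_chromosome(self) -> np.ndarray:
        """Boolean mask over markers located on labeled sex chromosomes."""
        return np.array([str(c).upper() in {"X", "Y", "XY"} for c in self.chromosomes])
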