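"""In-memory container for the wide-format longitudinal cohort."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import SpecValidationError

N_WAVES = 3
#: wave time coding; Table-style growth coefficients assume t = 0, 1, 2
WAVE_TIMES = (0.0, 1.0, 2.0)

CTS_MAX = 24


@dataclass
class LongitudinalDataset:
    """One row per subject: three-wave PTS scores (waves 2-3 may be missing),
    childhood physical abuse score (0-24, optionally item-level), SNP dosages
    (0/1/2 copies of the minor allele, NaN = missing), age, gender
    (female = 1), two ancestry principal components, and — for synthetic
    cohorts — the latent generating class."""

    subject_id: np.ndarray
    pts: np.ndarray  # (n, 3) float, NaN = wave missing
    cts_total: np.ndarray  # (n,) float in [0, 24]
    dosages: np.ndarray  # (n, n_snps) float in {0,1,2}, NaN = missing
    snp_names: tuple
    age: np.ndarray
    gender: np.ndarray
    ancestry_pcs: np.ndarray  # (n, 2)
    cts_items: Optional[np.ndarray] = None  # (n, 6) ints 0-4
    true_class: Optional[np.ndarray] = None
    class_labels: Optional[tuple] = None

    def __post_init__(self):
        self.subject_id = np.asarray(self.subject_id)
        self.pts = np.asarray(self.pts, dtype=float)
        self.cts_total = np.asarray(self.cts_total, dtype=float)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.gender = np.asarray(self.gender, dtype=float)
        self.ancestry_pcs = np.asarray(self.ancestry_pcs, dtype=float)
        if self.cts_items is not None:
            self.cts_items = np.asarray(self.cts_items, dtype=float)
        if self.true_class is not None:
            self.true_class = np.asarray(self.true_class, dtype=int)
        self.validate()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)

    @property
    def wave_mask(self) -> np.ndarray:
        """(n, 3) bool, True where the wave score is observed."""
        return ~np.isnan(self.pts)

    def validate(self) -> None:
        n = self.n_subjects
        if self.pts.shape != (n, N_WAVES):
            raise SpecValidationError("pts_scores", f"expected shape ({n}, {N_WAVES})")
        if np.any(np.isnan(self.pts[:, 0])):
            raise SpecValidationError(
                "pts_scores", "wave-1 score must be observed for every subject"
            )
        obs = self.cts_total[~np.isnan(self.cts_total)]
        if np.any((obs < 0) | (obs > CTS_MAX)):
            raise SpecValidationError("cts_total", f"values must lie in [0, {CTS_MAX}]")
        if self.cts_items is not None:
            if self.cts_items.shape != (n, 6):
                raise SpecValidationError("cts_items", f"expected shape ({n}, 6)")
            sums = self.cts_items.sum(axis=1)
            ok = np.isnan(sums) | np.isnan(self.cts_total) | (np.abs(sums - self.cts_total) < 1e-9)
            if not np.all(ok):
                raise SpecValidationError("cts_items", "item sums disagree with cts_total")
        d = self.dosages
        if d.shape[0] != n or len(self.snp_names) != d.shape[1]:
            raise SpecValidationError("genotype_dosages", "shape/snp_names mismatch")
        obs_d = d[~np.isnan(d)]
        if not np.all(np.isin(obs_d, (0.0, 1.0, 2.0))):
            raise SpecValidationError("genotype_dosages", "dosages must be 0, 1, or 2")
        for name, arr in (("age", self.age), ("gender", self.gender)):
            if arr.shape != (n,):
                raise SpecValidationError(name, f"expected shape ({n},)")
        if self.ancestry_pcs.shape != (n, 2):
            raise SpecValidationError("ancestry_pcs", f"expected shape ({n}, 2)")

    def to_frame(self) -> pd.DataFrame:
        """Wide per-subject table (the phenotype file layout)."""
        cols = {"subject_id": self.subject_id}
        for w in range(N_WAVES):
            cols[f"pts_w{w + 1}"] = self.pts[:, w]
        if self.cts_items is not None:
            for j in range(6):
                cols[f"cts_{j + 1}"] = self.cts_items[:, j]
        cols["cts_total"] = self.cts_total
        cols["age"] = self.age
        cols["gender"] = self.gender
        cols["pc1"] = self.ancestry_pcs[:, 0]
        cols["pc2"] = self.ancestry_pcs[:, 1]
        if self.true_class is not None:
            cols["true_class"] = self.true_class
        return pd.DataFrame(cols)

    def genotype_frame(self) -> pd.DataFrame:
        cols = {"subject_id": self.subject_id}
        for j, name in enumerate(self.snp_names):
            cols[name] = self.dosages[:, j]
        return pd.DataFrame(cols)
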