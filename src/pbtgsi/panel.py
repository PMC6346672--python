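"""SNP panel description: locus ids, allele codes, analytic flags."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LocusPanel:
    """A biallelic SNP panel.

    Parameters
    ----------
    locus_ids
        Unique locus names, one per SNP.
    allele_codes
        Integer array of shape ``(n_loci, 2)``; the two valid allele codes
        per locus. Genotypes are stored as the dosage of the *second* code.
    is_analytic
        Boolean array; loci flagged ``False`` (e.g. species-ID or sex-ID
        markers) are excluded from parentage and stock-identification work.
    """

    locus_ids: tuple[str, ...]
    allele_codes: np.ndarray
    is_analytic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "locus_ids", tuple(str(x) for x in self.locus_ids))
        codes = np.asarray(self.allele_codes, dtype=np.int64)
        if codes.shape != (len(self.locus_ids), 2):
            raise ValueError(
                f"allele_codes must have shape ({len(self.locus_ids)}, 2), got {codes.shape}"
            )
        if np.any(codes[:, 0] == codes[:, 1]):
            bad = self.locus_ids[int(np.argmax(codes[:, 0] == codes[:, 1]))]
            raise ValueError(f"locus {bad!r} has identical allele codes")
        object.__setattr__(self, "allele_codes", codes)
        if self.is_analytic is None:
            flags = np.ones(len(self.locus_ids), dtype=bool)
        else:
            flags = np.asarray(self.is_analytic, dtype=bool)
        if flags.shape != (len(self.locus_ids),):
            raise ValueError("is_analytic must be one flag per locus")
        object.__setattr__(self, "is_analytic", flags)
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus_ids must be unique")
        if len(self.locus_ids) == 0 or not flags.any():
            raise ValueError("panel must contain at least one analytic locus")

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def index_of(self, locus: str) -> int:
        return self.locus_ids.index(locus)

    def analytic_subset(self) -> "LocusPanel":
        """Return the panel restricted to analytic loci (order preserved)."""
        keep = self.is_analytic
        return LocusPanel(
            tuple(l for l, k in zip(self.locus_ids, keep) if k),
            self.allele_codes[keep],
            np.ones(int(keep.sum()), dtype=bool),
        )

    @classmethod
    def default(cls, n_loci: int = 302, n_non_analytic: int = 0) -> "LocusPanel":
        """Synthetic panel with loci ``L0001..`` and allele codes (1, 2).

        The first ``n_non_analytic`` loci are flagged non-analytic.
        """
        total = n_loci + n_non_analytic
        ids = tuple(f"L{i + 1:04d}" for i in range(total))
        codes = np.tile([1, 2], (total, 1))
        flags = np.ones(total, dtype=bool)
        flags[:n_non_analytic] = False
        return cls(ids, codes, flags)

    @classmethod
    def from_csv(cls, path) -> "LocusPanel":
        df = pd.read_csv(path)
        required = {"locus", "allele_1", "allele_2"}
        if not required.issubset(df.columns):
            raise ValueError(f"panel file must have columns {sorted(required)}")
        flags = (
            df["analytic"].astype(bool).to_numpy()
            if "analytic" in df.columns
            else np.ones(len(df), dtype=bool)
        )
        return cls(
            tuple(df["locus"].astype(str)),
            df[["allele_1", "allele_2"]].to_numpy(dtype=np.int64),
            flags,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "locus": self.locus_ids,
                "allele_1": self.allele_codes[:, 0],
                "allele_2": self.allele_codes[:, 1],
                "analytic": self.is_analytic.astype(int),
            }
        ).to_csv(path, index=False)
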