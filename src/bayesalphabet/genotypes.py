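"""Genotype container for multi-breed SNP panels.

The central in-memory object is :class:`GenotypeMatrix`: an animals x SNPs
dosage store (count of the reference allele, 0/1/2, fractional after mean
imputation) with an explicit missingness mask, per-animal breed and sire
labels, and a coding state.  Two codings exist:

``dosage``
    Raw allele counts in {0, 1, 2} (fractional once imputed).
``centered-ten``
    The whole-genome regression coding AA = 10, AB = 0, BB = -10,
    i.e. ``10 * (dosage - 1)``.  Fractional dosages map linearly.

All frequency computations exclude masked entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DOSAGE = "dosage"
CENTERED_TEN = "centered-ten"


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage store with missingness mask and labels.

    Parameters
    ----------
    dosages : ndarray, shape (n_animals, n_snps)
        Allele counts (or centered-ten values, per ``coding``).
    mask : ndarray of bool, same shape
        True marks a missing (uncalled) genotype.  Masked entries keep
        whatever value sits in ``dosages`` but are excluded from all
        statistics.
    animal_ids, snp_ids : sequences of str
        Unique identifiers along each axis.
    breed, sire : sequences of str
        Per-animal sire-breed label and sire id (empty strings allowed).
    coding : {"dosage", "centered-ten"}
    """

    dosages: np.ndarray
    mask: np.ndarray = None
    animal_ids: np.ndarray = None
    snp_ids: np.ndarray = None
    breed: np.ndarray = None
    sire: np.ndarray = None
    coding: str = DOSAGE

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D animals x SNPs array")
        n, k = self.dosages.shape
        if self.mask is None:
            self.mask = np.zeros((n, k), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.dosages.shape:
            raise ValueError("mask shape must match dosages shape")
        if self.animal_ids is None:
            self.animal_ids = np.array([f"A{i:06d}" for i in range(n)])
        if self.snp_ids is None:
            self.snp_ids = np.array([f"SNP{j:06d}" for j in range(k)])
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        if len(self.animal_ids) != n or len(self.snp_ids) != k:
            raise ValueError("id lengths must match matrix dimensions")
        if len(set(self.animal_ids)) != n or len(set(self.snp_ids)) != k:
            raise ValueError("animal and SNP ids must be unique")
        if self.breed is None:
            self.breed = np.array([""] * n, dtype=object)
        if self.sire is None:
            self.sire = np.array([""] * n, dtype=object)
        self.breed = np.asarray(self.breed, dtype=object)
        self.sire = np.asarray(self.sire, dtype=object)
        if len(self.breed) != n or len(self.sire) != n:
            raise ValueError("breed/sire labels must have one entry per animal")
        if self.coding not in (DOSAGE, CENTERED_TEN):
            raise ValueError(f"unknown coding state {self.coding!r}")

    # -- basic geometry -------------------------------------------------

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            dosages=self.dosages.copy(),
            mask=self.mask.copy(),
            animal_ids=self.animal_ids.copy(),
            snp_ids=self.snp_ids.copy(),
            breed=self.breed.copy(),
            sire=self.sire.copy(),
        )

    def subset(self, animals=None, snps=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given index arrays (positions
        or boolean masks) along either axis."""
        ai = np.arange(self.n_animals) if animals is None else np.asarray(animals)
        si = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if ai.dtype == bool:
            ai = np.flatnonzero(ai)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(ai, si)],
            mask=self.mask[np.ix_(ai, si)],
            animal_ids=self.animal_ids[ai],
            snp_ids=self.snp_ids[si],
            breed=self.breed[ai],
            sire=self.sire[ai],
            coding=self.coding,
        )

    # -- frequency statistics ------------------------------------------

    def allele_frequencies(self) -> np.ndarray:
        """Reference-allele frequency per SNP from called entries only.

        Returns NaN for SNPs with no called animals.  Requires dosage coding.
        """
        self._require(DOSAGE)
        called = ~self.mask
        n_called = called.sum(axis=0).astype(float)
        total = np.where(self.mask, 0.0, self.dosages).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = total / (2.0 * n_called)
        p[n_called == 0] = np.nan
        return p

    def values_centered_ten(self) -> np.ndarray:
        """The centered-ten view of the matrix (no state change)."""
        if self.coding == CENTERED_TEN:
            return self.dosages
        return 10.0 * (self.dosages - 1.0)

    def _require(self, coding: str):
        if self.coding != coding:
            raise ValueError(
                f"operation requires coding state {coding!r}, "
                f"matrix is {self.coding!r}"
            )
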