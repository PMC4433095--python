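"""Tab-delimited file dialect for genotypes, phenotypes and truth tables.

Every file starts with a one-line ``#`` metadata header carrying the
package version and the generating seed.  Genotypes are written as an
animals x SNPs dosage table (first column ``animal_id``, header row of SNP
ids, missing as ``NA``) with a sidecar SNP info file (id, chrom, pos).
Phenotype/pedigree tables use the columns animal_id, sire_id, breed, herd,
sex, date, plus trait values.  A PLINK additive-coded text export
(``--recode A``) can be imported onto the same store.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

FORMAT_VERSION = "bayesalphabet/1"


def _header(seed) -> str:
    return f"# {FORMAT_VERSION} seed={seed}\n"


def write_genotypes(gm: GenotypeMatrix, path, seed="NA", sidecar=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("animal_id\t" + "\t".join(map(str, gm.snp_ids)) + "\n")
        for i in range(gm.n_animals):
            vals = [
                "NA" if gm.mask[i, j] else _fmt(gm.dosages[i, j])
                for j in range(gm.n_snps)
            ]
            fh.write(str(gm.animal_ids[i]) + "\t" + "\t".join(vals) + "\n")
    if sidecar is not None:
        write_snp_info(gm, sidecar, seed=seed)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:.6g}"


def write_snp_info(gm: GenotypeMatrix, path, seed="NA") -> None:
    """Sidecar SNP table with synthetic map positions (29 autosomes,
    SNPs laid out in storage order)."""
    k = gm.n_snps
    chrom = (np.arange(k) % 29) + 1
    pos = (np.arange(k) // 29 + 1) * 10_000
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("snp_id\tchrom\tpos\n")
        for j in range(k):
            fh.write(f"{gm.snp_ids[j]}\t{chrom[j]}\t{pos[j]}\n")


def read_genotypes(path, pedigree: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"animal_id": str})
    df = df.set_index("animal_id")
    dos = df.to_numpy(dtype=float)
    mask = np.isnan(dos)
    dos = np.nan_to_num(dos, nan=0.0)
    breed = sire = None
    if pedigree is not None:
        ped = pedigree.set_index("animal_id").loc[df.index]
        breed = ped["breed"].to_numpy(dtype=object)
        sire = ped["sire_id"].to_numpy(dtype=object)
    return GenotypeMatrix(
        dosages=dos,
        mask=mask,
        animal_ids=df.index.to_numpy(dtype=object),
        snp_ids=df.columns.to_numpy(dtype=object),
        breed=breed,
        sire=sire,
    )


def write_table(df: pd.DataFrame, path, seed="NA") -> None:
    """Phenotype/pedigree/truth tables in the shared dialect."""
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_truth(path, alpha, g, cg, ve, seed="NA") -> None:
    """Simulation truth: marker effects and per-animal genetic/cg values;
    the residual variance rides in the metadata line."""
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} seed={seed} ve={ve}\n")
        fh.write("kind\tindex\tvalue\n")
        for j, a in enumerate(np.asarray(alpha, dtype=float)):
            fh.write(f"alpha\t{j}\t{float(a)!r}\n")
        for i, v in enumerate(np.asarray(g, dtype=float)):
            fh.write(f"g\t{i}\t{float(v)!r}\n")
        for i, v in enumerate(np.asarray(cg, dtype=float)):
            fh.write(f"cg\t{i}\t{float(v)!r}\n")


def read_plink_raw(path) -> GenotypeMatrix:
    """Import a PLINK ``--recode A`` additive text export (0/1/2 dosages,
    NA missing) onto the genotype store."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
            if c in df.columns]
    ids = df["IID"].astype(str).to_numpy(dtype=object)
    snp_cols = [c for c in df.columns if c not in meta]
    dos = df[snp_cols].to_numpy(dtype=float)
    mask = np.isnan(dos)
    # strip the PLINK _<allele> suffix from SNP names when present
    snp_ids = np.array(
        [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols], dtype=object
    )
    return GenotypeMatrix(
        dosages=np.nan_to_num(dos, nan=0.0),
        mask=mask,
        animal_ids=ids,
        snp_ids=snp_ids,
    )
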