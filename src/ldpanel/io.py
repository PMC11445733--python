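"""Readers and writers for the standard interchange formats.

Internal polarity is always minor-allele dosage: both readers re-polarize
on load (counting the rarer allele, ties broken toward the alphabetically
first allele) and record the flipped markers in the bundle metadata.
Positions are 1-based as in MAP/VCF; marker order comes from the map.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, DatasetBundle, GenotypeMatrix, MarkerMap, Pedigree

_PED_MISSING = "0"


def write_plink(bundle: DatasetBundle, ped_path, map_path) -> None:
    """PLINK text PED/MAP; unknown parents and missing genotypes are '0'."""
    mmap = bundle.marker_map.table
    with open(map_path, "w") as fh:
        for row in mmap.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.marker}\t{row.cm:g}\t{row.bp}\n")

    a = mmap["allele_a"].to_numpy()
    b = mmap["allele_b"].to_numpy()
    # genotype strings per dosage: 0 -> b b, 1 -> a b, 2 -> a a
    geno_str = np.empty((4, len(mmap)), dtype=object)
    geno_str[0] = [f"{x} {x}" for x in b]
    geno_str[1] = [f"{x} {y}" for x, y in zip(a, b)]
    geno_str[2] = [f"{x} {x}" for x in a]
    geno_str[3] = ["0 0"] * len(mmap)

    ped = bundle.pedigree
    labels = bundle.population_labels
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(bundle.genotypes.individuals):
            sire, dam = (ped.parents_of(ind) if ped is not None else (None, None))
            fam = ind
            if ped is not None:
                rec = ped.table.loc[ped.table["individual"] == ind, "family"]
                if len(rec) and rec.iloc[0] is not None:
                    fam = rec.iloc[0]
                elif labels is not None and ind in labels.index:
                    fam = labels[ind]
            d = bundle.genotypes.dosages[i]
            idx = np.where(d == MISSING, 3, d).astype(int)
            cells = geno_str[idx, np.arange(len(mmap))]
            fh.write("\t".join([str(fam), str(ind), str(sire or "0"), str(dam or "0"),
                                "0", "-9", *cells]) + "\n")


def _minor_allele(counts: dict[str, int]) -> tuple[str, str]:
    """(counted minor allele, other allele); ties -> alphabetically first."""
    alleles = sorted(counts)
    if len(alleles) == 1:
        return ("A" if alleles[0] != "A" else "B"), alleles[0]
    (a1, a2) = alleles
    if counts[a1] < counts[a2] or (counts[a1] == counts[a2]):
        return a1, a2
    return a2, a1


def read_plink(ped_path, map_path) -> DatasetBundle:
    """Load PED/MAP, recoding genotypes to minor-allele dosage."""
    map_rows = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chrom, marker, cm, bp = parts[:4]
            map_rows.append((marker, int(chrom), int(bp), float(cm)))
    n_markers = len(map_rows)

    inds, sires, dams, fams = [], [], [], []
    allele_rows = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(f"PED line {ln}: expected {6 + 2 * n_markers} fields, "
                                 f"got {len(parts)}")
            fams.append(parts[0])
            inds.append(parts[1])
            sires.append(None if parts[2] == _PED_MISSING else parts[2])
            dams.append(None if parts[3] == _PED_MISSING else parts[3])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(inds), n_markers, 2)

    dosages = np.zeros((len(inds), n_markers), dtype=np.int8)
    allele_a, allele_b = [], []
    for j in range(n_markers):
        col = alleles[:, j, :]
        observed = col[col != _PED_MISSING]
        uniq, cnt = np.unique(observed, return_counts=True)
        if uniq.size > 2:
            raise ValueError(f"marker {map_rows[j][0]} is not biallelic: {uniq.tolist()}")
        counts = dict(zip(uniq.tolist(), cnt.tolist()))
        if not counts:
            allele_a.append("A")
            allele_b.append("B")
            dosages[:, j] = MISSING
            continue
        minor, major = _minor_allele(counts)
        allele_a.append(minor)
        allele_b.append(major)
        miss = (col == _PED_MISSING).any(axis=1)
        dosages[:, j] = (col == minor).sum(axis=1).astype(np.int8)
        dosages[miss, j] = MISSING

    tab = pd.DataFrame(
        [(mk, c, bp, cm, a, b) for (mk, c, bp, cm), a, b in zip(map_rows, allele_a, allele_b)],
        columns=list(MarkerMap.COLUMNS))
    mmap = MarkerMap(tab)
    geno = GenotypeMatrix(dosages, inds, mmap.markers)
    known = set(inds)
    ped_records = [(i, s if s in known else None, d if d in known else None,
                    f if f != i else None)
                   for i, s, d, f in zip(inds, sires, dams, fams)]
    pedigree = Pedigree(pd.DataFrame(ped_records,
                                     columns=["individual", "sire", "dam", "family"]))
    return DatasetBundle(geno, mmap, pedigree,
                         metadata={"source": str(ped_path), "format": "plink"})


def write_vcf(bundle: DatasetBundle, path) -> None:
    """Minimal VCF v4.2 with GT only; REF is the major allele, ALT the
    counted minor allele, genetic position carried in INFO/CM."""
    g = bundle.genotypes
    mmap = bundle.marker_map.table
    gt_str = np.array(["0/0", "0/1", "1/1", "./."])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in bundle.marker_map.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(i) for i in g.individuals) + "\n")
        d = g.dosages
        idx = np.where(d == MISSING, 3, d).astype(int)
        for j, row in enumerate(mmap.itertuples(index=False)):
            cells = gt_str[idx[:, j]]
            fh.write(f"{row.chrom}\t{row.bp}\t{row.marker}\t{row.allele_b}\t"
                     f"{row.allele_a}\t.\tPASS\tCM={row.cm:g}\tGT\t"
                     + "\t".join(cells) + "\n")


def read_vcf(path) -> DatasetBundle:
    """Load a biallelic GT-only VCF, re-polarizing dosage to the minor
    allele (flips are recorded in ``metadata['flipped_markers']``)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array([gt[:2] for gt in var.genotypes], dtype=int)
        miss = (gts < 0).any(axis=1)
        d = gts.clip(0).sum(axis=1).astype(np.int8)
        d[miss] = MISSING
        cm = var.INFO.get("CM", 0.0) or 0.0
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", int(var.CHROM), var.POS,
                     float(cm), var.ALT[0], var.REF))
        dosage_cols.append(d)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic records")
    dosages = np.stack(dosage_cols, axis=1) if dosage_cols else \
        np.zeros((len(samples), 0), dtype=np.int8)

    flipped = []
    allele_a = [r[4] for r in rows]
    allele_b = [r[5] for r in rows]
    for j in range(dosages.shape[1]):
        d = dosages[:, j]
        obs = d != MISSING
        if obs.any():
            f = d[obs].sum() / (2.0 * obs.sum())
            if f > 0.5:
                dosages[obs, j] = 2 - d[obs]
                allele_a[j], allele_b[j] = allele_b[j], allele_a[j]
                flipped.append(rows[j][0])
    tab = pd.DataFrame(
        [(mk, c, bp, cm, a, b) for (mk, c, bp, cm, _, _), a, b in zip(rows, allele_a, allele_b)],
        columns=list(MarkerMap.COLUMNS))
    mmap = MarkerMap(tab)
    geno = GenotypeMatrix(dosages, samples, mmap.markers)
    return DatasetBundle(geno, mmap, None,
                         metadata={"source": str(path), "format": "vcf",
                                   "flipped_markers": flipped,
                                   "skipped_multiallelic": n_multi})


def write_pedigree_tsv(ped: Pedigree, path) -> None:
    tab = ped.table.fillna("0")
    tab.to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> Pedigree:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    tab = tab.replace("0", None)
    return Pedigree(tab)


def write_labels_tsv(labels: pd.Series, path) -> None:
    labels.rename("population").rename_axis("individual").to_csv(path, sep="\t")


def read_labels_tsv(path) -> pd.Series:
    tab = pd.read_csv(path, sep="\t", dtype=str).set_index("individual")
    return tab["population"]


def write_bundle(bundle: DatasetBundle, out_dir, prefix: str = "dataset") -> dict:
    """Write PED/MAP + VCF + pedigree/label TSVs; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": out / f"{prefix}.ped",
        "map": out / f"{prefix}.map",
        "vcf": out / f"{prefix}.vcf",
    }
    write_plink(bundle, paths["ped"], paths["map"])
    write_vcf(bundle, paths["vcf"])
    if bundle.pedigree is not None:
        paths["pedigree"] = out / f"{prefix}.pedigree.tsv"
        write_pedigree_tsv(bundle.pedigree, paths["pedigree"])
    if bundle.population_labels is not None:
        paths["labels"] = out / f"{prefix}.labels.tsv"
        write_labels_tsv(bundle.population_labels, paths["labels"])
    return {k: str(v) for k, v in paths.items()}
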