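"""Readers/writers for the pipeline's file formats and the shared data model.

The central container is :class:`GenotypePanel`: a sites x individuals matrix
of biallelic diploid genotypes with group membership and group roles
(``wild``, ``domestic_A``, ``domestic_B``, ``world_panel``).  All coordinates
are 1-based inclusive internally (VCF convention); BED I/O converts at the
boundary.

Only biallelic SNPs without missing genotypes are representable: the study
design compares fully genotyped call sets, so the VCF reader drops
multi-allelic and indel records (with a logged count) and refuses missing
genotypes rather than imputing them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

SCAN_ROLES = ("wild", "domestic_A", "domestic_B")
ALL_ROLES = SCAN_ROLES + ("world_panel",)


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# GenotypePanel
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Biallelic SNP genotypes for a set of grouped individuals.

    Parameters
    ----------
    sites : DataFrame with columns ``chrom, pos, ref, alt`` (pos 1-based),
        strictly increasing within each chromosome.
    genotypes : int8 array of shape (n_sites, n_individuals, 2) with allele
        indices in {0, 1}.
    individuals : sample identifiers, one per genotype column.
    groups : mapping individual -> group label.
    roles : mapping group label -> role (one of ``ALL_ROLES``).
    phased : whether the two allele columns are haplotypes.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    individuals: list[str]
    groups: dict[str, str]
    roles: dict[str, str]
    phased: bool = True

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (sites, individuals, 2)")
        if self.genotypes.shape[0] != len(self.sites):
            raise ValueError("site table and genotype matrix disagree on n_sites")
        if self.genotypes.shape[1] != len(self.individuals):
            raise ValueError("individuals and genotype matrix disagree")
        missing = [i for i in self.individuals if i not in self.groups]
        if missing:
            raise ValueError(f"individuals without group assignment: {missing}")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def group_members(self, group: str) -> list[str]:
        return [i for i in self.individuals if self.groups[i] == group]

    def group_columns(self, group: str) -> np.ndarray:
        idx = [j for j, i in enumerate(self.individuals) if self.groups[i] == group]
        if not idx:
            raise KeyError(f"group not present in panel: {group}")
        return np.asarray(idx, dtype=int)

    def group_for_role(self, role: str) -> str:
        hits = [g for g, r in self.roles.items() if r == role]
        if len(hits) != 1:
            raise KeyError(f"expected exactly one group with role {role!r}, found {hits}")
        return hits[0]

    def scan_groups(self) -> list[str]:
        """The three groups entering the selection scan (wild + two domestics)."""
        return [self.group_for_role(r) for r in SCAN_ROLES]

    def haplotypes(self, columns: np.ndarray | None = None) -> np.ndarray:
        """Haplotype matrix (n_sites, 2*n) for the given individual columns."""
        g = self.genotypes if columns is None else self.genotypes[:, columns, :]
        return g.reshape(g.shape[0], -1)

    def alt_freq(self, group: str | None = None) -> np.ndarray:
        """Per-site ALT allele frequency within a group (or overall)."""
        cols = None if group is None else self.group_columns(group)
        h = self.haplotypes(cols)
        return h.mean(axis=1)

    def alt_dosage(self, columns: np.ndarray | None = None) -> np.ndarray:
        g = self.genotypes if columns is None else self.genotypes[:, columns, :]
        return g.sum(axis=2)

    # -- subsetting ---------------------------------------------------------

    def take_sites(self, index: np.ndarray) -> "GenotypePanel":
        sites = self.sites.iloc[index].reset_index(drop=True)
        return replace(self, sites=sites, genotypes=self.genotypes[index])

    def subset_interval(self, chrom: str, start: int, end: int) -> "GenotypePanel":
        """Sites with start <= pos <= end on chrom (1-based inclusive)."""
        m = (
            (self.sites["chrom"] == chrom)
            & (self.sites["pos"] >= start)
            & (self.sites["pos"] <= end)
        ).to_numpy()
        return self.take_sites(np.flatnonzero(m))

    def site_mask_interval(self, chrom: str, start: int, end: int) -> np.ndarray:
        return (
            (self.sites["chrom"] == chrom)
            & (self.sites["pos"] >= start)
            & (self.sites["pos"] <= end)
        ).to_numpy()

    def unphased_copy(self) -> "GenotypePanel":
        """Return a copy with allele order randomized away (sorted) and phase flag off."""
        g = np.sort(self.genotypes, axis=2)
        return replace(self, genotypes=g, phased=False)


# ---------------------------------------------------------------------------
# VCF + groups table
# ---------------------------------------------------------------------------

def read_groups(path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a groups TSV with columns individual, group, role."""
    tbl = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "group", "role"}
    if not required.issubset(tbl.columns):
        raise FormatError(f"groups table must have columns {sorted(required)}")
    groups = dict(zip(tbl["individual"], tbl["group"]))
    roles: dict[str, str] = {}
    for g, r in zip(tbl["group"], tbl["role"]):
        if g in roles and roles[g] != r:
            raise FormatError(f"group {g} assigned conflicting roles")
        if r not in ALL_ROLES:
            raise FormatError(f"unknown role {r!r} for group {g}")
        roles[g] = r
    return groups, roles


def write_groups(path, groups: dict[str, str], roles: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tgroup\trole\n")
        for ind, grp in groups.items():
            fh.write(f"{ind}\t{grp}\t{roles[grp]}\n")


def read_vcf(path, groups_path) -> GenotypePanel:
    """Load a VCF into a :class:`GenotypePanel`.

    Multi-allelic and indel records are dropped (count logged).  Missing
    genotypes are fatal: the pipeline expects complete call sets.
    """
    groups, roles = read_groups(groups_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in groups]
    if unknown:
        raise FormatError(f"VCF samples missing from groups table: {unknown}")

    chroms, poss, refs, alts = [], [], [], []
    geno_rows = []
    n_dropped = 0
    phased = True
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        gt = np.asarray(var.genotype.array())  # (n, 3): a0, a1, phased flag
        if np.any(gt[:, :2] < 0):
            raise FormatError(f"missing genotype at {var.CHROM}:{var.POS}")
        phased = phased and bool(np.all(gt[:, 2] == 1))
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        geno_rows.append(gt[:, :2].astype(np.int8))
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    if not geno_rows:
        raise FormatError(f"no biallelic SNP records in {path}")
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    genotypes = np.stack(geno_rows)
    return GenotypePanel(sites, genotypes, samples, groups, roles, phased=phased)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write a deterministic, minimal VCF 4.2 with GT-only genotypes."""
    sep = "|" if panel.phased else "/"
    contigs = list(dict.fromkeys(panel.sites["chrom"]))
    lengths = {
        c: int(panel.sites.loc[panel.sites["chrom"] == c, "pos"].max())
        for c in contigs
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=domescan\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length={lengths[c] + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individuals)
            + "\n"
        )
        sites = panel.sites
        G = panel.genotypes
        for i in range(panel.n_sites):
            row = sites.iloc[i]
            gts = "\t".join(f"{a}{sep}{b}" for a, b in G[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

def filter_sites(
    panel: GenotypePanel,
    maf_min: float = 0.10,
    scan_groups: list[str] | None = None,
) -> GenotypePanel:
    """Retain sites with MAF strictly above ``maf_min`` in at least one scan group.

    Sites monomorphic across all retained individuals are also removed.  The
    default scan groups are the wild group and the two traditional domestic
    groups.
    """
    if scan_groups is None:
        scan_groups = panel.scan_groups()
    keep = np.zeros(panel.n_sites, dtype=bool)
    for g in scan_groups:
        f = panel.alt_freq(g)
        maf = np.minimum(f, 1.0 - f)
        keep |= maf > maf_min
    overall = panel.alt_freq()
    keep &= (overall > 0.0) & (overall < 1.0)
    if not keep.any():
        raise FormatError(
            "filter_sites removed every site "
            f"(maf_min={maf_min}, groups={scan_groups})"
        )
    logger.info("filter_sites: kept %d / %d sites", int(keep.sum()), panel.n_sites)
    return panel.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Homology map
# ---------------------------------------------------------------------------

@dataclass
class HomologyMap:
    """Aligned segment pairs linking two genome coordinate systems.

    ``segments`` has columns ``chrom1, start1, end1, chrom2, start2, end2,
    strand`` (1-based inclusive; strand '+' or '-').  Source segments must be
    non-overlapping and each pair must have equal length.
    """

    segments: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        seg = self.segments
        if len(seg) == 0:
            return
        if np.any(
            (seg["end1"] - seg["start1"]) != (seg["end2"] - seg["start2"])
        ):
            raise FormatError("homology segments must pair equal lengths")
        for chrom, sub in seg.sort_values("start1").groupby("chrom1"):
            s, e = sub["start1"].to_numpy(), sub["end1"].to_numpy()
            if np.any(s[1:] <= e[:-1]):
                raise FormatError(f"overlapping source segments on {chrom}")

    def map_position(self, chrom: str, pos: int):
        """Map a source position; returns (chrom2, pos2) or None if unmapped."""
        seg = self.segments
        if len(seg) == 0:
            return None
        hit = seg[(seg["chrom1"] == chrom) & (seg["start1"] <= pos) & (seg["end1"] >= pos)]
        if len(hit) == 0:
            return None
        r = hit.iloc[0]
        off = pos - r["start1"]
        if r["strand"] == "+":
            return r["chrom2"], int(r["start2"] + off)
        return r["chrom2"], int(r["end2"] - off)

    def map_interval(self, chrom: str, start: int, end: int) -> list[tuple[str, int, int]]:
        """Image of [start, end] as a list of target intervals (may be empty)."""
        out = []
        seg = self.segments
        if len(seg) == 0:
            return out
        sub = seg[(seg["chrom1"] == chrom) & (seg["start1"] <= end) & (seg["end1"] >= start)]
        for _, r in sub.iterrows():
            s = max(start, int(r["start1"]))
            e = min(end, int(r["end1"]))
            if r["strand"] == "+":
                t0 = int(r["start2"] + (s - r["start1"]))
                t1 = int(r["start2"] + (e - r["start1"]))
            else:
                t0 = int(r["end2"] - (e - r["start1"]))
                t1 = int(r["end2"] - (s - r["start1"]))
            out.append((r["chrom2"], t0, t1))
        return out

    def inverse(self) -> "HomologyMap":
        seg = self.segments.rename(
            columns={
                "chrom1": "chrom2", "start1": "start2", "end1": "end2",
                "chrom2": "chrom1", "start2": "start1", "end2": "end1",
            }
        )[["chrom1", "start1", "end1", "chrom2", "start2", "end2", "strand"]]
        return HomologyMap(seg.reset_index(drop=True))


def read_homology(path) -> HomologyMap:
    seg = pd.read_csv(path, sep="\t")
    seg["chrom1"] = seg["chrom1"].astype(str)
    seg["chrom2"] = seg["chrom2"].astype(str)
    return HomologyMap(seg)


def write_homology(hmap: HomologyMap, path) -> None:
    hmap.segments.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene track
# ---------------------------------------------------------------------------

@dataclass
class GeneTrack:
    """Gene records: columns chrom, start, end, strand, name (1-based inclusive)."""

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.genes) and np.any(self.genes["start"] > self.genes["end"]):
            raise FormatError("gene with start > end")


def read_genes_bed(path) -> GeneTrack:
    """BED4+ (0-based half-open) -> GeneTrack (1-based inclusive)."""
    tbl = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = pd.DataFrame(
        {
            "chrom": tbl[0].astype(str),
            "start": tbl[1].astype(int) + 1,
            "end": tbl[2].astype(int),
            "strand": tbl[5] if tbl.shape[1] > 5 else "+",
            "name": tbl[3].astype(str) if tbl.shape[1] > 3 else "",
        }
    )
    return GeneTrack(genes)


def write_genes_bed(track: GeneTrack, path) -> None:
    with open(path, "w") as fh:
        for _, g in track.genes.iterrows():
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g['name']}\t0\t{g.strand}\n")


def read_genes_gff3(path) -> GeneTrack:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name", attrs.get("ID", ""))
            rows.append((f[0], int(f[3]), int(f[4]), f[6], name))
    return GeneTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"]))


# ---------------------------------------------------------------------------
# Conservation scores
# ---------------------------------------------------------------------------

def read_conservation(path) -> pd.DataFrame:
    """TSV with columns chrom, pos, score (per-site conservation, phyloP-like)."""
    tbl = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos", "score"}.issubset(tbl.columns):
        raise FormatError("conservation table needs columns chrom, pos, score")
    tbl["chrom"] = tbl["chrom"].astype(str)
    return tbl


def write_conservation(tbl: pd.DataFrame, path) -> None:
    tbl.to_csv(path, sep="\t", index=False, float_format="%.4f")
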