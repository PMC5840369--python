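"""Synthetic paired two-genus datasets with planted selection signatures.

The generator emulates the sampling design of a two-genus domestication
study: per genus, one wild group, two traditionally managed domestic groups,
and a multi-breed world panel.  Population allele frequencies drift from a
shared ancestral frequency along a rooted population tree under the
Balding-Nichols construction (each branch perturbs frequencies with variance
c * p * (1 - p) for branch drift c).  Within each population, haplotypes are
mosaics of a finite founder pool, which creates linkage disequilibrium
without a coalescent dependency.

Selective sweeps are planted by replacing a fraction (the *intensity*) of
target-group haplotypes with a single founder haplotype inside an interval.
``domestic_sweep`` targets the domestic groups (optionally the world panel),
``relaxation`` is modeled as the mirror event -- a sweep in the wild group
only -- so that domestic diversity exceeds wild diversity locally.  A subset
of sweeps can be marked shared across the two genera; the homology plan then
guarantees they fall in aligned segments.

Everything is seeded: identical scenario + seed gives byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .io import GenotypePanel, GeneTrack, HomologyMap, SCAN_ROLES

# role -> (group label per genus)
ROLE_GROUPS = {
    1: {"wild": "WILD1", "domestic_A": "DOMA1", "domestic_B": "DOMB1", "world_panel": "WP1"},
    2: {"wild": "WILD2", "domestic_A": "DOMA2", "domestic_B": "DOMB2", "world_panel": "WP2"},
}

DEFAULT_GROUP_SIZES = {"wild": 15, "domestic_A": 20, "domestic_B": 20, "world_panel": 14}

# Rooted population tree as nested tuples: (name, branch_drift, children).
# Leaves are role names.  Drift amounts are Reynolds-scale and dimensionless.
DEFAULT_POP_TREE = (
    "root",
    0.0,
    (
        ("wild", 0.04, ()),
        (
            "dom_anc",
            0.03,
            (
                ("domestic_A", 0.03, ()),
                ("domestic_B", 0.03, ()),
                ("world_panel", 0.06, ()),
            ),
        ),
    ),
)


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: replace ``intensity`` of target haplotypes in an interval."""

    genus: int
    chrom: str
    start: int
    end: int
    target_roles: tuple[str, ...]
    intensity: float
    mode: str = "domestic_sweep"  # domestic_sweep | wild_sweep | relaxation
    shared_id: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"sweep intensity {self.intensity} outside [0, 1]")
        if self.start > self.end:
            raise ValueError("sweep interval start > end")


@dataclass
class LoadSpec:
    """Density and distribution of deleterious (constrained) sites and load shifts."""

    genes_per_chrom: int = 30
    constrained_fraction: float = 0.3   # of genic sites
    score_scale: float = 1.0            # constrained score = 1.5 + Exp(score_scale)
    shifted_fraction: float = 0.0       # fraction of genes with planted excess load
    shift_hom_prob: float = 0.3         # per-site prob of planting hom-ALT in shifted genes
    shift_roles: tuple[str, ...] = ("domestic_A", "domestic_B")
    hom_coupling: float = 0.0           # couple planted load to individual homozygosity

    def __post_init__(self):
        if not 0.0 <= self.constrained_fraction <= 1.0:
            raise ValueError("constrained_fraction outside [0, 1]")


@dataclass
class SimScenario:
    seed: int
    n_snps_per_chrom: int = 1000
    chrom_lengths: tuple[int, ...] = (10_000_000, 10_000_000)
    pop_tree: tuple = DEFAULT_POP_TREE
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    ancestral_pool_size: int = 30
    switch_rate: float = 1e-5
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    # per-individual inbreeding f ~ Uniform(range): fraction of sites where
    # the second haplotype is overwritten by the first (autozygosity)
    inbreeding_range: tuple[float, float] = (0.0, 0.0)
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    load_spec: LoadSpec = field(default_factory=LoadSpec)
    # homology plan: rows (chrom1, start1, end1, chrom2, start2, strand)
    homology_plan: list[tuple] | None = None
    phased_output: bool = True

    def __post_init__(self):
        for role, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group size for {role} must be >= 2")
        for d in _tree_drifts(self.pop_tree):
            if not 0.0 < d < 1.0:
                raise ValueError(f"branch drift {d} outside (0, 1)")

    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(len(self.chrom_lengths))]


@dataclass
class SweepTruth:
    """Ledger of realized planted sweeps."""

    sweeps: list[dict] = field(default_factory=list)

    def for_genus(self, genus: int) -> list[dict]:
        return [s for s in self.sweeps if s["genus"] == genus]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.sweeps, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SweepTruth":
        with open(path) as fh:
            return cls(json.load(fh))


def _tree_drifts(node) -> list[float]:
    _, drift, children = node
    out = [drift] if drift > 0 else []
    for ch in children:
        out.extend(_tree_drifts(ch))
    return out


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, c: float) -> np.ndarray:
    """Drift frequencies one branch: Beta with mean p and variance c p (1-p)."""
    if c <= 0:
        return p.copy()
    a = p * (1.0 - c) / c
    b = (1.0 - p) * (1.0 - c) / c
    out = rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))
    return np.clip(out, 1e-9, 1.0 - 1e-9)


def _leaf_freqs(rng, node, p, out) -> None:
    name, drift, children = node
    q = _balding_nichols(rng, p, drift)
    if not children:
        out[name] = q
    for ch in children:
        _leaf_freqs(rng, ch, q, out)


def _mosaic_haplotypes(
    rng: np.random.Generator,
    pool: np.ndarray,
    positions: np.ndarray,
    n_hap: int,
    switch_rate: float,
) -> np.ndarray:
    """Build n_hap mosaic haplotypes (sites x n_hap) from a founder pool (sites x P)."""
    n_sites, P = pool.shape
    ids = np.empty((n_sites, n_hap), dtype=np.int32)
    ids[0] = rng.integers(0, P, size=n_hap)
    if n_sites > 1:
        dist = np.diff(positions).astype(float)
        p_switch = 1.0 - np.exp(-switch_rate * dist)
        switch = rng.random((n_sites - 1, n_hap)) < p_switch[:, None]
        new_ids = rng.integers(0, P, size=(n_sites - 1, n_hap))
        for s in range(1, n_sites):
            ids[s] = np.where(switch[s - 1], new_ids[s - 1], ids[s - 1])
    return pool[np.arange(n_sites)[:, None], ids]


def simulate_genus(
    scenario: SimScenario, genus: int
) -> tuple[GenotypePanel, SweepTruth]:
    """Simulate one genus: phased diploid genotypes plus the sweep truth ledger."""
    if genus not in (1, 2):
        raise ValueError("genus must be 1 or 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), genus]))
    group_of = ROLE_GROUPS[genus]
    roles = {group_of[r]: r for r in scenario.group_sizes}
    chroms = scenario.chrom_names()

    for sw in scenario.sweep_specs:
        if sw.genus != genus:
            continue
        ci = chroms.index(sw.chrom) if sw.chrom in chroms else -1
        if ci < 0 or sw.end > scenario.chrom_lengths[ci]:
            raise ValueError(f"sweep interval outside simulated coordinates: {sw}")

    site_frames, hap_blocks = [], []
    pools: dict[tuple[str, str], np.ndarray] = {}
    site_offsets = {}
    for ci, chrom in enumerate(chroms):
        L = scenario.chrom_lengths[ci]
        S = scenario.n_snps_per_chrom
        positions = np.sort(rng.choice(np.arange(1, L + 1), size=S, replace=False))
        p_anc = rng.uniform(*scenario.ancestral_freq_range, size=S)
        leaf_freq: dict[str, np.ndarray] = {}
        _leaf_freqs(rng, scenario.pop_tree, p_anc, leaf_freq)

        hap_cols = {}
        for role, n in scenario.group_sizes.items():
            pool = (
                rng.random((S, scenario.ancestral_pool_size)) < leaf_freq[role][:, None]
            ).astype(np.int8)
            pools[(chrom, role)] = pool
            hap_cols[role] = _mosaic_haplotypes(
                rng, pool, positions, 2 * n, scenario.switch_rate
            )
        ref = rng.choice(list("ACGT"), size=S)
        alt_shift = rng.integers(1, 4, size=S)
        bases = np.array(list("ACGT"))
        base_idx = np.searchsorted(bases, ref)
        alt = bases[(base_idx + alt_shift) % 4]
        site_frames.append(
            pd.DataFrame({"chrom": chrom, "pos": positions, "ref": ref, "alt": alt})
        )
        site_offsets[chrom] = sum(len(f) for f in site_frames[:-1])
        hap_blocks.append(hap_cols)

    # assemble genome-wide haplotype matrix per role
    role_order = list(scenario.group_sizes)
    haps = {
        role: np.concatenate([blk[role] for blk in hap_blocks], axis=0)
        for role in role_order
    }
    sites = pd.concat(site_frames, ignore_index=True)

    # plant sweeps
    truth = SweepTruth()
    for sw in scenario.sweep_specs:
        if sw.genus != genus:
            continue
        targets = (
            ("wild",) if sw.mode == "relaxation" else tuple(sw.target_roles)
        )
        mask = (
            (sites["chrom"] == sw.chrom)
            & (sites["pos"] >= sw.start)
            & (sites["pos"] <= sw.end)
        ).to_numpy()
        idx = np.flatnonzero(mask)
        founder_id = int(rng.integers(0, scenario.ancestral_pool_size))
        donor_pool = pools[(sw.chrom, targets[0])]
        chrom_idx = idx - site_offsets[sw.chrom]
        sweep_hap = donor_pool[chrom_idx, founder_id]
        for role in targets:
            H = haps[role]
            hit = rng.random(H.shape[1]) < sw.intensity
            H[np.ix_(idx, np.flatnonzero(hit))] = sweep_hap[:, None]
        rec = asdict(sw)
        rec["founder_id"] = founder_id
        rec["realized_targets"] = list(targets)
        truth.sweeps.append(rec)

    # pack into a panel
    individuals, groups, cols = [], {}, []
    for role in role_order:
        grp = group_of[role]
        n = scenario.group_sizes[role]
        for j in range(n):
            individuals.append(f"{grp}_{j:02d}")
            groups[individuals[-1]] = grp
        cols.append(haps[role].reshape(haps[role].shape[0], n, 2))
    genotypes = np.concatenate(cols, axis=1)
    lo, hi = scenario.inbreeding_range
    if hi > 0:
        f_ind = rng.uniform(lo, hi, size=genotypes.shape[1])
        auto = rng.random(genotypes.shape[:2]) < f_ind[None, :]
        genotypes[:, :, 1] = np.where(auto, genotypes[:, :, 0], genotypes[:, :, 1])
    panel = GenotypePanel(sites, genotypes, individuals, groups, roles, phased=True)
    if not scenario.phased_output:
        panel = panel.unphased_copy()
    return panel, truth


# ---------------------------------------------------------------------------
# Homology map
# ---------------------------------------------------------------------------

def default_homology_plan(scenario: SimScenario) -> list[tuple]:
    """Identity map on chromosome 1 (where sweeps live); gap + offset on the rest.

    Covers >= 90% of genus-1 coordinates so every shared sweep lies in a
    mapped segment.
    """
    plan = []
    for ci, chrom in enumerate(scenario.chrom_names()):
        L = scenario.chrom_lengths[ci]
        if ci == 0:
            plan.append((chrom, 1, L, chrom, 1, "+"))
        else:
            cut = int(L * 0.45)
            gap_end = int(L * 0.50)
            plan.append((chrom, 1, cut, chrom, 1, "+"))
            plan.append((chrom, gap_end + 1, L, chrom, gap_end + 10_001, "+"))
    return plan


def simulate_homology_map(scenario: SimScenario) -> HomologyMap:
    plan = scenario.homology_plan
    if plan is None:
        plan = default_homology_plan(scenario)
    rows = []
    for chrom1, start1, end1, chrom2, start2, strand in plan:
        rows.append(
            {
                "chrom1": chrom1, "start1": int(start1), "end1": int(end1),
                "chrom2": chrom2, "start2": int(start2),
                "end2": int(start2) + (int(end1) - int(start1)),
                "strand": strand,
            }
        )
    return HomologyMap(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Conservation scores, genes, and planted genetic load
# ---------------------------------------------------------------------------

@dataclass
class ConsLoadResult:
    panel: GenotypePanel          # copy with planted load genotypes
    conservation: pd.DataFrame    # chrom, pos, score
    genes: GeneTrack
    truth: dict                   # shifted_genes, parameters


def simulate_conservation_and_load(
    scenario: SimScenario, panel: GenotypePanel, genus: int = 1
) -> ConsLoadResult:
    """Per-site conservation scores, a tiled gene track, and planted load shifts.

    Genes tile alternate blocks of consecutive SNPs.  A fraction of genic
    sites is constrained (score >= 1.5, scores 1.5 + Exponential); the rest
    score below the constraint threshold.  Designated load-shifted genes
    receive excess homozygous derived (ALT) genotypes in the shift-target
    groups; with ``hom_coupling`` > 0, extra homozygous-derived genotypes are
    planted genome-wide with per-individual probability proportional to that
    individual's homozygosity, which guarantees a positive inbreeding-load
    relationship downstream.
    """
    spec = scenario.load_spec
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), genus, 7]))
    sites = panel.sites
    G = panel.genotypes.copy()

    gene_rows, gene_site_idx = [], {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        Sc = len(idx)
        block = max(2, Sc // (2 * spec.genes_per_chrom))
        for g in range(spec.genes_per_chrom):
            i0 = 2 * g * block
            i1 = i0 + block - 1
            if i1 >= Sc:
                break
            name = f"G{genus}_{chrom}_{g:04d}"
            gidx = idx[i0 : i1 + 1]
            gene_site_idx[name] = gidx
            gene_rows.append(
                (chrom, int(sites["pos"].iloc[gidx[0]]), int(sites["pos"].iloc[gidx[-1]]), "+", name)
            )
    genes = GeneTrack(
        pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "name"])
    )

    genic = np.zeros(len(sites), dtype=bool)
    for gidx in gene_site_idx.values():
        genic[gidx] = True
    constrained = genic & (rng.random(len(sites)) < spec.constrained_fraction)
    scores = rng.uniform(-2.0, 1.4, size=len(sites))
    scores[constrained] = 1.5 + rng.exponential(spec.score_scale, size=int(constrained.sum()))
    conservation = pd.DataFrame(
        {"chrom": sites["chrom"], "pos": sites["pos"], "score": np.round(scores, 4)}
    )

    # load-shifted genes: excess homozygous-derived genotypes in target groups
    names = list(gene_site_idx)
    n_shift = int(round(spec.shifted_fraction * len(names)))
    shifted = sorted(rng.choice(names, size=n_shift, replace=False)) if n_shift else []
    target_cols = np.concatenate(
        [panel.group_columns(panel.group_for_role(r)) for r in spec.shift_roles]
    ) if n_shift else np.array([], dtype=int)
    for name in shifted:
        gidx = gene_site_idx[name]
        cidx = gidx[constrained[gidx]]
        if len(cidx) == 0:
            continue
        hit = rng.random((len(cidx), len(target_cols))) < spec.shift_hom_prob
        rows, cols = np.nonzero(hit)
        G[cidx[rows], target_cols[cols], :] = 1

    if spec.hom_coupling > 0:
        # Inbreeding exposes deleterious variants: homozygous-derived
        # genotypes are planted at constrained sites with a per-individual
        # probability proportional to *excess* homozygosity (min-max scaled
        # within the panel), which guarantees a monotone F vs
        # load-per-homozygous-position relationship downstream.
        hom = (panel.genotypes[:, :, 0] == panel.genotypes[:, :, 1]).mean(axis=0)
        rel = (hom - hom.min()) / max(hom.max() - hom.min(), 1e-9)
        p_ind = np.clip(spec.hom_coupling * rel, 0.0, 1.0)
        cidx = np.flatnonzero(constrained)
        hit = rng.random((len(cidx), panel.n_individuals)) < p_ind[None, :]
        rows, cols = np.nonzero(hit)
        G[cidx[rows], cols, :] = 1

    truth = {
        "shifted_genes": list(shifted),
        "constrained_fraction": spec.constrained_fraction,
        "shift_hom_prob": spec.shift_hom_prob,
        "hom_coupling": spec.hom_coupling,
        "gene_sites": {k: v.tolist() for k, v in gene_site_idx.items()},
    }
    out_panel = replace(panel, genotypes=G)
    return ConsLoadResult(out_panel, conservation, genes, truth)


# ---------------------------------------------------------------------------
# Scenario builders used by tests, the acceptance script, and the CLI demo
# ---------------------------------------------------------------------------

def demo_scenario(
    seed: int,
    n_snps_per_chrom: int = 1000,
    chrom_lengths: tuple[int, ...] = (10_000_000, 10_000_000),
    n_shared_sweeps: int = 3,
    n_specific_sweeps: int = 3,
    n_relaxation: int = 0,
    intensity: float = 0.9,
    specific_intensities: list[float] | None = None,
    sweep_span: int = 300_000,
    include_world_panel_in_sweeps: bool = True,
    **overrides,
) -> SimScenario:
    """Two-genus scenario with sweeps on chromosome 1 and a neutral chromosome 2.

    Shared sweeps occupy the same (identity-mapped) slots in both genera;
    genus-specific sweeps occupy disjoint slots so they are not homologous to
    any sweep in the other genus.  Relaxation events are wild-group sweeps.
    ``specific_intensities`` optionally grades the genus-specific sweeps
    (e.g. weaker local-adaptation signals next to strong shared
    domestication targets -- the regime in which the convergence curve is
    informative); by default all sweeps use ``intensity``.
    """
    scn = SimScenario(seed=seed, n_snps_per_chrom=n_snps_per_chrom,
                      chrom_lengths=chrom_lengths, **overrides)
    L = chrom_lengths[0]
    per_genus = n_shared_sweeps + n_specific_sweeps + n_relaxation
    n_slots = n_shared_sweeps + 2 * (n_specific_sweeps + n_relaxation)
    if per_genus == 0:
        return scn
    lo, hi = int(0.05 * L), int(0.95 * L)
    slot_w = (hi - lo) // max(n_slots, 1)
    if slot_w <= sweep_span:
        raise ValueError("chromosome too short for the requested sweeps")

    def slot(i: int) -> tuple[int, int]:
        s = lo + i * slot_w
        return s, s + sweep_span - 1

    dom_targets = ("domestic_A", "domestic_B") + (
        ("world_panel",) if include_world_panel_in_sweeps else ()
    )
    specs: list[SweepSpec] = []
    k = 0
    for i in range(n_shared_sweeps):
        s, e = slot(k); k += 1
        for genus in (1, 2):
            specs.append(SweepSpec(genus, "1", s, e, dom_targets, intensity,
                                   "domestic_sweep", shared_id=f"SH{i}"))
    spec_int = specific_intensities or [intensity] * n_specific_sweeps
    if len(spec_int) != n_specific_sweeps:
        raise ValueError("specific_intensities length mismatch")
    for genus in (1, 2):
        for i in range(n_specific_sweeps):
            s, e = slot(k); k += 1
            specs.append(SweepSpec(genus, "1", s, e, dom_targets, spec_int[i],
                                   "domestic_sweep"))
    for genus in (1, 2):
        for _ in range(n_relaxation):
            s, e = slot(k); k += 1
            specs.append(SweepSpec(genus, "1", s, e, ("wild",), intensity,
                                   "relaxation"))
    scn.sweep_specs = specs
    return scn
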