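"""Synthetic hexaploid panels with known truth.

The generator emulates the data structure of an inter-varietal 454 survey
of a hexaploid crop: each "gene family" exists as three diverged
homoeologous copies (one per subgenome), bi-allelic inter-varietal SNPs are
planted on exactly one copy each, and varieties contribute pyrosequencing-
like reads with substitution (and optional homopolymer-indel) errors.
RIL populations, monosomic F1 hybrid genotype panels and two-dose DArT
hybridization intensities are generated on the same global seed so every
downstream stage can be tested against recorded truth.

All generators are pure functions of (config, seed): one global seed is
fanned out to fixed per-stage streams so stages can be re-run in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .formats import GenotypeMatrix, LinkageMap, Read

_BASES = np.array(list("ACGT"))

# fixed per-stage stream ids, fanned out from the global seed
_STAGE_PANEL = 11
_STAGE_READS = 22
_STAGE_RIL = 33
_STAGE_MONO = 44
_STAGE_DOSE = 55


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


@dataclass
class SimulationConfig:
    """Knobs for the synthetic panel; defaults mirror the study design at
    desk scale: 20 varieties, 200 cDNA-like templates of 600 bp in three
    subgenomes, coverage 8 reads per template copy per variety."""

    seed: int
    n_templates: int = 200
    template_length: int = 600
    n_subgenomes: int = 3
    subgenome_divergence: float = 0.16  # pairwise fraction between homoeologs
    n_varieties: int = 20
    snp_density: int = 2  # planted SNPs per template family
    allele_frequency_spectrum: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    read_length_mean: float = 350.0
    read_length_sd: float = 50.0
    coverage_per_variety: float = 8.0  # mean reads per template copy
    error_rate_sub: float = 0.002
    error_rate_homopolymer_indel: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("subgenome_divergence", "error_rate_sub",
                     "error_rate_homopolymer_indel"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_templates", "template_length", "n_subgenomes",
                     "n_varieties", "snp_density"):
            if getattr(self, name) <= 0 and name != "snp_density":
                raise ValueError(f"{name} must be positive")
        if not all(0.0 < f < 1.0 for f in self.allele_frequency_spectrum):
            raise ValueError("allele frequencies must lie in (0, 1)")
        # divergence + planted SNPs must fit in the sequence
        budget = (self.subgenome_divergence + 0.02) * self.template_length \
            + self.snp_density
        if budget > self.template_length / 2:
            raise ValueError(
                "subgenome_divergence and snp_density jointly exceed "
                "sequence capacity"
            )

    @property
    def varieties(self) -> list[str]:
        return [f"var{i:02d}" for i in range(self.n_varieties)]


@dataclass
class PlantedSnp:
    template: str  # homoeolog copy id
    position: int  # 1-based on the copy
    ref: str
    alt: str
    carriers: frozenset[str]


@dataclass
class HomoeologFamily:
    family: str
    copies: list[str]
    divergent_positions: frozenset[int]  # 1-based; columns where copies differ


@dataclass
class TruthTable:
    """Ground truth emitted by the generators; consumed only in assertions."""

    snps: list[PlantedSnp] = field(default_factory=list)
    families: list[HomoeologFamily] = field(default_factory=list)
    ril_genotypes: GenotypeMatrix | None = None
    stock_chromosomes: dict[str, str] = field(default_factory=dict)
    nominal_stock_chromosomes: dict[str, str] = field(default_factory=dict)
    reduced_dose: set[tuple[str, str]] = field(default_factory=set)

    def snps_by_template(self) -> dict[str, list[PlantedSnp]]:
        out: dict[str, list[PlantedSnp]] = {}
        for s in self.snps:
            out.setdefault(s.template, []).append(s)
        return out

    def to_json(self) -> str:
        payload = {
            "snps": [
                {**asdict(s), "carriers": sorted(s.carriers)} for s in self.snps
            ],
            "families": [
                {**asdict(f),
                 "divergent_positions": sorted(f.divergent_positions)}
                for f in self.families
            ],
            "stock_chromosomes": self.stock_chromosomes,
            "nominal_stock_chromosomes": self.nominal_stock_chromosomes,
            "reduced_dose": sorted(map(list, self.reduced_dose)),
        }
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# panel + reads


def _mutate(rng, seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
    out = seq.copy()
    shift = rng.integers(1, 4, size=len(positions))
    idx = (np.searchsorted(_BASES, out[positions]) + shift) % 4
    out[positions] = _BASES[idx]
    return out


def simulate_panel(config: SimulationConfig):
    """Generate per-variety haplotypes and the planted truth.

    Returns ``(haplotypes, truth)`` where ``haplotypes[variety][copy_id]``
    is the sequence of that variety's homoeolog copy.  Copies of a family
    diverge by substitutions only (same length, shared coordinates); each
    planted inter-varietal SNP sits on exactly one copy at a column where
    all copies otherwise agree, and its carriers are a non-empty proper
    subset of the panel drawn from the configured frequency spectrum.
    """
    rng = _rng(config.seed, _STAGE_PANEL)
    L = config.template_length
    varieties = config.varieties
    truth = TruthTable()
    # per-copy mutation rate so that pairwise divergence ~= configured value
    per_copy = config.subgenome_divergence / 2.0

    haplotypes: dict[str, dict[str, np.ndarray]] = {v: {} for v in varieties}
    for t in range(config.n_templates):
        family = f"fam{t:04d}"
        ancestor = rng.choice(_BASES, size=L)
        copies: dict[str, np.ndarray] = {}
        for s in range(config.n_subgenomes):
            cid = f"{family}_s{s}"
            n_mut = rng.binomial(L, per_copy)
            pos = rng.choice(L, size=n_mut, replace=False)
            copies[cid] = _mutate(rng, ancestor, pos)
        stack = np.stack(list(copies.values()))
        divergent = np.where((stack != stack[0]).any(axis=0))[0]
        truth.families.append(HomoeologFamily(
            family, sorted(copies), frozenset((divergent + 1).tolist())))

        # plant SNPs on conserved columns, one copy each
        conserved = np.setdiff1d(np.arange(L), divergent)
        n_snp = min(config.snp_density, len(conserved))
        snp_pos = rng.choice(conserved, size=n_snp, replace=False)
        variant: dict[str, list[tuple[int, str, frozenset]]] = {
            c: [] for c in copies
        }
        for p in snp_pos:
            cid = sorted(copies)[rng.integers(config.n_subgenomes)]
            ref = copies[cid][p]
            alt = _BASES[(np.searchsorted(_BASES, ref) + rng.integers(1, 4)) % 4]
            f_target = config.allele_frequency_spectrum[
                rng.integers(len(config.allele_frequency_spectrum))
            ]
            while True:
                k = rng.binomial(config.n_varieties, f_target)
                if 0 < k < config.n_varieties:
                    break
            carriers = frozenset(
                rng.choice(varieties, size=k, replace=False).tolist())
            truth.snps.append(
                PlantedSnp(cid, int(p) + 1, str(ref), str(alt), carriers))
            variant[cid].append((int(p), str(alt), carriers))

        for v in varieties:
            for cid, seq in copies.items():
                hap = seq
                carried = [(p, alt) for p, alt, car in variant[cid] if v in car]
                if carried:
                    hap = hap.copy()
                    for p, alt in carried:
                        hap[p] = alt
                haplotypes[v][cid] = hap

    out = {
        v: {cid: "".join(seq) for cid, seq in copies.items()}
        for v, copies in haplotypes.items()
    }
    return out, truth


def _inject_errors(rng, seq: str, sub_rate: float, hp_rate: float) -> str:
    arr = np.array(list(seq))
    if sub_rate > 0:
        n = rng.binomial(len(arr), sub_rate)
        if n:
            pos = rng.choice(len(arr), size=n, replace=False)
            arr = _mutate(rng, arr, pos)
    s = "".join(arr)
    if hp_rate > 0:
        # per homopolymer run, occasionally slip by one base (454 signature)
        out = []
        i = 0
        while i < len(s):
            j = i
            while j < len(s) and s[j] == s[i]:
                j += 1
            run = s[i:j]
            if rng.random() < hp_rate:
                run = run + s[i] if rng.random() < 0.5 else run[:-1]
            out.append(run)
            i = j
        s = "".join(out)
    return s


def simulate_reads(haplotypes, config: SimulationConfig) -> list[Read]:
    """Draw 454-like reads uniformly across template copies per variety.

    Read counts per (variety, copy) are Poisson(coverage_per_variety);
    lengths are normal (clipped to the template); the read id encodes its
    true origin as ``variety.copy.n`` for truth-table assertions.
    """
    rng = _rng(config.seed, _STAGE_READS)
    reads: list[Read] = []
    for v in sorted(haplotypes):
        for cid in sorted(haplotypes[v]):
            hap = haplotypes[v][cid]
            n = rng.poisson(config.coverage_per_variety)
            for k in range(n):
                L = int(round(rng.normal(config.read_length_mean,
                                         config.read_length_sd)))
                L = max(50, min(L, len(hap)))
                start = int(rng.integers(0, len(hap) - L + 1))
                seq = _inject_errors(
                    rng, hap[start : start + L],
                    config.error_rate_sub,
                    config.error_rate_homopolymer_indel,
                )
                reads.append(Read(f"{v}.{cid}.{k}", v, seq))
    return reads


# ---------------------------------------------------------------------------
# RIL populations


def haldane_r(d_cm: float) -> float:
    """Haldane map function: cM interval -> meiotic recombination fraction."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def ril_observed_r(r: float) -> float:
    """Expected observed recombinant fraction between selfed-RIL genotypes."""
    return 2.0 * r / (1.0 + 2.0 * r)


def simulate_ril_population(lmap: LinkageMap, n_ril: int, seed: int,
                            missing_rate: float = 0.0,
                            error_rate: float = 0.0) -> GenotypeMatrix:
    """Fully homozygous selfed-RIL genotypes on a given genetic map.

    Transmission is simulated marker-to-marker (Markov): the first marker
    of each group is A/B with probability 1/2 and each adjacent interval
    switches parent with probability R = 2r/(1+2r), r from the Haldane
    inverse of the cM distance.  Groups are independent.
    """
    if lmap.entries.empty:
        raise ValueError("empty linkage map")
    rng = _rng(seed, _STAGE_RIL)
    cols: dict[str, np.ndarray] = {}
    order: list[str] = []
    for g in lmap.groups:
        sub = lmap.markers_of(g)
        markers = sub["marker"].tolist()
        pos = sub["position_cm"].to_numpy()
        state = rng.integers(0, 2, size=n_ril)
        cols[markers[0]] = state.copy()
        for i in range(1, len(markers)):
            R = ril_observed_r(haldane_r(pos[i] - pos[i - 1]))
            flip = rng.random(n_ril) < R
            state = np.where(flip, 1 - state, state)
            cols[markers[i]] = state.copy()
        order.extend(markers)
    calls = np.where(np.column_stack([cols[m] for m in order]) == 0, "A", "B")
    if error_rate > 0:
        flip = rng.random(calls.shape) < error_rate
        calls = np.where(flip, np.where(calls == "A", "B", "A"), calls)
    if missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < missing_rate, "U", calls)
    samples = [f"ril{i:04d}" for i in range(n_ril)]
    return GenotypeMatrix(pd.DataFrame(calls, index=samples, columns=order))


# ---------------------------------------------------------------------------
# monosomic F1 hybrid panel


def simulate_monosomic_panel(lmap: LinkageMap, stocks,
                             noise: float = 0.0, seed: int = 0,
                             shift_fraction: float = 0.0):
    """Genotype calls for F1 hybrids of monosomic stocks x a euploid parent.

    ``stocks`` maps stock id -> nominally missing chromosome (a linkage
    group of the map); a list of ``anchoring.MonosomicStock`` records is
    accepted as well.  Every map locus is informative (maternal A,
    paternal B): the F1 call is the paternal homozygous call B at loci on
    the stock's missing chromosome (the hemizygous signature) and H
    elsewhere.  ``noise`` is a per-call miscall probability (replaced by a
    uniform draw of the other two calls); ``shift_fraction`` of stocks have
    their critical chromosome replaced by another group (univalent shift).

    Returns ``(maternal_calls, paternal_calls, f1, truth)`` where the
    parent calls are per-locus Series.
    """
    if not isinstance(stocks, dict):
        stocks = {s.stock_id: s.missing_chromosome for s in stocks}
    groups = lmap.groups
    for stock, chrom in stocks.items():
        if chrom not in groups:
            raise ValueError(f"stock {stock!r} names group {chrom!r} "
                             "absent from the map")
    rng = _rng(seed, _STAGE_MONO)
    loci = lmap.entries["marker"].tolist()
    group_of = lmap.group_of()
    truth = TruthTable(nominal_stock_chromosomes=dict(stocks))

    actual: dict[str, str] = {}
    stock_ids = sorted(stocks)
    n_shift = int(round(shift_fraction * len(stock_ids)))
    shifted = set(
        rng.choice(stock_ids, size=n_shift, replace=False).tolist()
    ) if n_shift else set()
    for stock in stock_ids:
        chrom = stocks[stock]
        if stock in shifted:
            others = [g for g in groups if g != chrom]
            chrom = others[int(rng.integers(len(others)))]
        actual[stock] = chrom
    truth.stock_chromosomes = actual

    calls = np.empty((len(stock_ids), len(loci)), dtype="<U1")
    for i, stock in enumerate(stock_ids):
        missing = actual[stock]
        for j, m in enumerate(loci):
            calls[i, j] = "B" if group_of[m] == missing else "H"
    if noise > 0:
        alphabet = np.array(list("ABH"))
        flip = rng.random(calls.shape) < noise
        for i, j in zip(*np.where(flip)):
            others = alphabet[alphabet != calls[i, j]]
            calls[i, j] = others[int(rng.integers(len(others)))]
    f1 = GenotypeMatrix(pd.DataFrame(calls, index=stock_ids, columns=loci))
    maternal = pd.Series("A", index=loci)
    paternal = pd.Series("B", index=loci)
    return maternal, paternal, f1, truth


# ---------------------------------------------------------------------------
# DArT intensities


def simulate_intensities(n_samples: int, representations, dose_map,
                         full_center: float = 1000.0, ratio: float = 0.5,
                         cv: float = 0.1, seed: int = 0):
    """Two-dose log-normal hybridization intensities.

    ``dose_map`` is a set of (sample, representation) pairs at reduced
    dose; their intensities are log-normal with mean ``ratio*full_center``,
    all others with mean ``full_center``, both with coefficient of
    variation ``cv``.  Returns ``(intensities, truth)``.
    """
    rng = _rng(seed, _STAGE_DOSE)
    samples = [f"s{i:03d}" for i in range(n_samples)]
    representations = list(representations)
    reduced = {(s, r) for s, r in dose_map}
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)

    values = np.empty((n_samples, len(representations)))
    for i, s in enumerate(samples):
        for j, r in enumerate(representations):
            center = full_center * (ratio if (s, r) in reduced else 1.0)
            mu = math.log(center) - sigma2 / 2.0
            values[i, j] = rng.lognormal(mu, sigma) if cv > 0 else center
    df = pd.DataFrame(values, index=samples, columns=representations)
    truth = TruthTable(reduced_dose=set(reduced))
    return df, truth
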