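"""Gene-drop simulator producing PED/MAP fixtures with known truth.

The generator emulates the statistical structure of a commercial-herd
case/control genotyping study: a few founder animals, two to three bred
generations with occasional consanguineous matings (so the genotyped cohort
is partially inbred and broadly related), a SNP map with physical positions,
and an implanted disease-associated haplotype whose carriers' phenotype risk
is set by penetrances.  Transmission is recorded per haplotype as founder
ancestry segments, so true autozygosity, true pairwise IBD and true carrier
status are available for parameter-recovery tests.

Recombination follows the Haldane (no-interference) model: crossover counts
are Poisson in the genetic map length, positions uniform on the cM map,
which defaults to 1 cM per Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from susgwas.genotype_io import (
    MISSING,
    PHENO_CASE,
    PHENO_CONTROL,
    PHENO_MISSING,
    GenotypeData,
    sort_markers,
    write_ped_map,
)


@dataclass
class RiskHaplotype:
    """An implanted haplotype and its penetrance model.

    The haplotype occupies ``n_markers`` consecutive markers centred on the
    chromosome and consists of the minor allele at each of them; founder
    haplotypes carry it with probability ``freq``.  Background minor-allele
    frequencies at those markers are drawn low (``span_bg_maf``), making the
    allele combination distinctive of the founding haplotype.  An animal
    carrying at least one intact copy is affected with probability
    ``penetrance_carrier``; non-carriers with ``penetrance_noncarrier``.
    The defaults emulate a strongly protective haplotype — essentially
    absent among affected animals while segregating widely in the herd —
    whose complement class is correspondingly enriched in cases.
    """

    chrom: str = "2"
    n_markers: int = 10
    freq: float = 0.35
    penetrance_carrier: float = 0.02
    penetrance_noncarrier: float = 0.70
    span_bg_maf: tuple[float, float] = (0.02, 0.08)

    def __post_init__(self) -> None:
        for v in (self.freq, self.penetrance_carrier, self.penetrance_noncarrier):
            if not 0.0 <= v <= 1.0:
                raise ValueError("frequencies and penetrances must be in [0, 1]")


@dataclass
class SimConfig:
    """Declarative description of the simulated population.

    Defaults are desk-scale: 18 autosomes of 300 markers plus an X of 150,
    founder minor-allele frequencies uniform on [0.05, 0.5], three bred
    generations over 20 founders, and a final cohort large enough to
    ascertain 35 cases and 18 controls under the risk-haplotype penetrances.
    """

    n_autosomes: int = 18
    markers_per_autosome: int = 300
    x_markers: int = 150
    autosome_length_bp: int = 130_000_000
    x_length_bp: int = 125_000_000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    n_founders: int = 40
    generation_sizes: tuple[int, ...] = (80, 160, 240)
    allow_sib_mating: bool = False
    cm_per_mb: float = 1.0
    risk: RiskHaplotype | None = field(default_factory=RiskHaplotype)
    n_cases: int = 35
    n_controls: int = 18
    missing_rate: float = 0.002
    seed: int = 0

    def chrom_labels(self) -> list[str]:
        labels = [str(c) for c in range(1, self.n_autosomes + 1)]
        if self.x_markers > 0:
            labels.append("X")
        return labels

    def chrom_length(self, chrom: str) -> int:
        return self.x_length_bp if chrom == "X" else self.autosome_length_bp

    def chrom_n_markers(self, chrom: str) -> int:
        return self.x_markers if chrom == "X" else self.markers_per_autosome

    def autosomal_genome_kb(self) -> float:
        return self.n_autosomes * self.autosome_length_bp / 1000.0


@dataclass
class SimTruth:
    """Ground truth recorded during the gene drop."""

    individuals: pd.DataFrame
    """per individual: iid, father, mother, generation, pedigree_f,
    autozygosity, carrier, n_implant_copies"""
    haplotypes: dict = field(repr=False, default_factory=dict)
    """iid -> {chrom: (hap0 segments, hap1 segments)}; a segment list is
    [(end_bp, founder_hap_id), ...] covering (prev_end, end_bp]"""
    founder_alleles: dict = field(repr=False, default_factory=dict)
    """chrom -> (2 * n_founders) x markers int8 allele matrix"""
    target_maf: dict = field(repr=False, default_factory=dict)
    """chrom -> per-marker founder minor-allele frequency targets"""
    implanted_founder_haps: set = field(default_factory=set)

    def carriers(self) -> list[str]:
        return list(self.individuals.loc[self.individuals["carrier"], "iid"])

    def true_ibd_fraction(self, iid1: str, iid2: str, chrom_lengths: dict) -> float:
        """Fraction of the diploid genome the pair shares IBD (half IBD1 + IBD2)."""
        total = 0.0
        shared = 0.0
        for chrom, length in chrom_lengths.items():
            h1 = self.haplotypes[iid1][chrom]
            h2 = self.haplotypes[iid2][chrom]
            total += length
            # expected IBD proportion at each bp: count matching source pairs / 4 * 2
            grid = _merged_breaks(list(h1) + list(h2))
            prev = 0
            for end in grid:
                mid = (prev + end) / 2.0
                sources1 = [_source_at(h1[0], mid), _source_at(h1[1], mid)]
                sources2 = [_source_at(h2[0], mid), _source_at(h2[1], mid)]
                matches = sum(1 for a in sources1 if a in sources2)
                shared += (end - prev) * min(matches, 2) / 2.0
                prev = end
        return shared / total if total else 0.0


def _merged_breaks(hap_lists) -> list[int]:
    ends = sorted({end for segs in hap_lists for end, _ in segs})
    return ends


def _source_at(segments, pos: float) -> int:
    for end, src in segments:
        if pos <= end:
            return src
    return segments[-1][1]


# ---------------------------------------------------------------------------
# meiosis on ancestry segments
# ---------------------------------------------------------------------------

def _recombine(hap_a, hap_b, length_bp: int, cm_per_mb: float, rng) -> list:
    """One gamete from a parent's two haplotypes under the Haldane model."""
    map_morgans = length_bp * 1e-6 * cm_per_mb / 100.0
    n_xo = rng.poisson(map_morgans)
    cuts = np.sort(rng.uniform(0, length_bp, size=n_xo)).astype(np.int64) if n_xo else np.array([], dtype=np.int64)
    current = int(rng.integers(2))
    haps = (hap_a, hap_b)
    out = []
    prev = 0
    for cut in list(cuts) + [length_bp]:
        cut = int(cut)
        if cut <= prev:
            current = 1 - current if cut < length_bp else current
            continue
        for end, src in haps[current]:
            if end <= prev:
                continue
            seg_end = min(end, cut)
            if out and out[-1][1] == src:
                out[-1] = (seg_end, src)
            else:
                out.append((seg_end, src))
            if seg_end == cut:
                break
        prev = cut
        current = 1 - current
    if out[-1][0] != length_bp:
        out[-1] = (length_bp, out[-1][1])
    return out


def _paint(segments, founder_alleles: np.ndarray, bp: np.ndarray) -> np.ndarray:
    """Allele vector for a haplotype from founder alleles and ancestry segments."""
    out = np.empty(len(bp), dtype=np.int8)
    prev = 0
    for end, src in segments:
        sel = (bp > prev) & (bp <= end)
        out[sel] = founder_alleles[src, sel]
        prev = end
    return out


def _autozygosity(hap_pair, length_bp: int) -> float:
    """Fraction of the chromosome where both haplotypes share a founder source."""
    h0, h1 = hap_pair
    grid = _merged_breaks([h0, h1])
    prev = 0
    auto = 0
    for end in grid:
        mid = (prev + end) / 2.0
        if _source_at(h0, mid) == _source_at(h1, mid):
            auto += end - prev
        prev = end
    return auto / length_bp


# ---------------------------------------------------------------------------
# pedigree construction and gene drop
# ---------------------------------------------------------------------------

def _pedigree_f(individuals: pd.DataFrame) -> np.ndarray:
    """Pedigree inbreeding coefficients via the tabular kinship method."""
    ids = list(individuals["iid"])
    idx = {iid: k for k, iid in enumerate(ids)}
    father = [idx.get(f, -1) for f in individuals["father"]]
    mother = [idx.get(m, -1) for m in individuals["mother"]]
    n = len(ids)
    phi = np.zeros((n, n))
    f = np.zeros(n)
    for i in range(n):
        fi, mi = father[i], mother[i]
        f[i] = phi[fi, mi] if fi >= 0 and mi >= 0 else 0.0
        phi[i, i] = 0.5 * (1.0 + f[i])
        for j in range(i):
            v = 0.0
            if fi >= 0:
                v += 0.5 * phi[fi, j]
            if mi >= 0:
                v += 0.5 * phi[mi, j]
            phi[i, j] = phi[j, i] = v
    return f


def simulate_population(config: SimConfig | None = None, seed: int | None = None):
    """Gene-drop a pedigreed population; returns (GenotypeData, SimTruth).

    The returned dataset holds the final-generation cohort with phenotype
    missing; :func:`assign_phenotypes` turns it into a case/control study.
    Founder haplotypes are drawn from the configured allele-frequency
    distribution, offspring haplotypes by Haldane-model recombination on the
    cM map, with full transmission records kept.  Deterministic under seed.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    chroms = cfg.chrom_labels()
    if cfg.risk is not None and cfg.risk.chrom not in chroms:
        raise ValueError(f"risk haplotype chromosome {cfg.risk.chrom!r} not on the map")
    if cfg.risk is not None and cfg.risk.n_markers > cfg.chrom_n_markers(cfg.risk.chrom):
        raise ValueError("risk haplotype span exceeds the chromosome's marker count")

    # marker map: evenly spaced with jitter, 1-based positions
    marker_rows = []
    bp_by_chrom: dict[str, np.ndarray] = {}
    for chrom in chroms:
        m = cfg.chrom_n_markers(chrom)
        length = cfg.chrom_length(chrom)
        spacing = length / (m + 1)
        bp = (spacing * np.arange(1, m + 1)
              + rng.uniform(-0.3 * spacing, 0.3 * spacing, size=m))
        bp = np.maximum(1, bp.astype(np.int64))
        bp = np.sort(bp)
        bp = np.unique(bp)
        while len(bp) < m:  # extremely unlikely collision fix-up
            extra = rng.integers(1, length, size=m - len(bp))
            bp = np.unique(np.concatenate([bp, extra]))
        bp_by_chrom[chrom] = bp
        for k, pos in enumerate(bp):
            marker_rows.append((chrom, f"SNP{chrom}_{k+1}", pos * 1e-6 * cfg.cm_per_mb, int(pos)))

    # founder allele matrices and implant
    n_fhap = 2 * cfg.n_founders
    founder_alleles: dict[str, np.ndarray] = {}
    maf_by_chrom: dict[str, np.ndarray] = {}
    lo, hi = cfg.founder_maf_range
    risk_span: np.ndarray | None = None
    implanted: set[int] = set()
    for chrom in chroms:
        m = len(bp_by_chrom[chrom])
        maf = rng.uniform(lo, hi, size=m)
        if cfg.risk is not None and chrom == cfg.risk.chrom:
            mid = m // 2
            half = cfg.risk.n_markers // 2
            span = np.arange(mid - half, mid - half + cfg.risk.n_markers)
            maf[span] = rng.uniform(*cfg.risk.span_bg_maf, size=len(span))
            risk_span = span
        maf_by_chrom[chrom] = maf
        alleles = (rng.random((n_fhap, m)) < maf[None, :]).astype(np.int8)
        if cfg.risk is not None and chrom == cfg.risk.chrom:
            carriers = np.flatnonzero(rng.random(n_fhap) < cfg.risk.freq)
            alleles[np.ix_(carriers, risk_span)] = 1
            implanted = set(int(c) for c in carriers)
        founder_alleles[chrom] = alleles

    # pedigree: founders then bred generations
    ped_rows = []       # iid, father, mother, generation
    haplotypes: dict[str, dict] = {}
    for i in range(cfg.n_founders):
        iid = f"F{i+1:03d}"
        ped_rows.append((iid, "0", "0", 0))
        haplotypes[iid] = {
            chrom: (
                [(cfg.chrom_length(chrom), 2 * i)],
                [(cfg.chrom_length(chrom), 2 * i + 1)],
            )
            for chrom in chroms
        }

    prev_gen = [r[0] for r in ped_rows]
    parents_of = {r[0]: ("0", "0") for r in ped_rows}
    for g, size in enumerate(cfg.generation_sizes, start=1):
        n_couples = max(1, len(prev_gen) // 2)
        shuffled = list(prev_gen)
        rng.shuffle(shuffled)
        couples = [(shuffled[2 * k], shuffled[2 * k + 1]) for k in range(n_couples)]
        if not cfg.allow_sib_mating:
            # re-pair any couple that are full sibs by swapping partners
            for k in range(len(couples)):
                a, b = couples[k]
                if parents_of[a] == parents_of[b] and parents_of[a] != ("0", "0"):
                    for k2 in range(len(couples)):
                        a2, b2 = couples[k2]
                        if k2 != k and parents_of[a] != parents_of[b2] and parents_of[a2] != parents_of[b]:
                            couples[k] = (a, b2)
                            couples[k2] = (a2, b)
                            break
        new_gen = []
        for c in range(size):
            sire, dam = couples[c % len(couples)]
            iid = f"G{g}_{c+1:03d}"
            ped_rows.append((iid, sire, dam, g))
            parents_of[iid] = (sire, dam)
            haplotypes[iid] = {}
            for chrom in chroms:
                length = cfg.chrom_length(chrom)
                hs = haplotypes[sire][chrom]
                hd = haplotypes[dam][chrom]
                haplotypes[iid][chrom] = (
                    _recombine(hs[0], hs[1], length, cfg.cm_per_mb, rng),
                    _recombine(hd[0], hd[1], length, cfg.cm_per_mb, rng),
                )
            new_gen.append(iid)
        prev_gen = new_gen

    individuals = pd.DataFrame(ped_rows, columns=["iid", "father", "mother", "generation"])
    individuals["pedigree_f"] = _pedigree_f(individuals)

    # realized autozygosity on the autosomes
    auto_chroms = [c for c in chroms if c != "X"]
    auto_total = sum(cfg.chrom_length(c) for c in auto_chroms)
    autoz = []
    for iid in individuals["iid"]:
        a = sum(
            _autozygosity(haplotypes[iid][c], cfg.chrom_length(c)) * cfg.chrom_length(c)
            for c in auto_chroms
        )
        autoz.append(a / auto_total)
    individuals["autozygosity"] = autoz

    # paint genotypes of the final cohort
    cohort = prev_gen
    markers = pd.DataFrame(marker_rows, columns=["chrom", "snp", "cm", "bp"])
    n_markers = len(markers)
    calls = np.zeros((len(cohort), n_markers), dtype=np.int8)
    col_offset = {}
    off = 0
    for chrom in chroms:
        col_offset[chrom] = off
        off += len(bp_by_chrom[chrom])
    carrier_flags = {}
    implant_copies = {}
    risk_string = None
    if cfg.risk is not None:
        risk_string = np.ones(cfg.risk.n_markers, dtype=np.int8)
    for i, iid in enumerate(cohort):
        copies = 0
        for chrom in chroms:
            bp = bp_by_chrom[chrom]
            h0, h1 = haplotypes[iid][chrom]
            a0 = _paint(h0, founder_alleles[chrom], bp)
            a1 = _paint(h1, founder_alleles[chrom], bp)
            sl = slice(col_offset[chrom], col_offset[chrom] + len(bp))
            calls[i, sl] = a0 + a1
            if cfg.risk is not None and chrom == cfg.risk.chrom:
                for hap_alleles in (a0, a1):
                    if np.array_equal(hap_alleles[risk_span], risk_string):
                        copies += 1
        carrier_flags[iid] = copies > 0
        implant_copies[iid] = copies
    individuals["carrier"] = [bool(carrier_flags.get(i, False)) for i in individuals["iid"]]
    individuals["n_implant_copies"] = [int(implant_copies.get(i, 0)) for i in individuals["iid"]]

    # missingness
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    # allele codes: a1 = minor ("A"), a2 = major ("G"); calls already count a1
    markers = markers.assign(a1="A", a2="G")
    samples = pd.DataFrame(
        {
            "fid": "HERD1",
            "iid": cohort,
            "father": [parents_of[i][0] for i in cohort],
            "mother": [parents_of[i][1] for i in cohort],
            "sex": 1,
            "phenotype": PHENO_MISSING,
        }
    )
    data = sort_markers(GenotypeData(calls=calls, markers=markers, samples=samples))
    truth = SimTruth(
        individuals=individuals,
        haplotypes=haplotypes,
        founder_alleles=founder_alleles,
        target_maf=maf_by_chrom,
        implanted_founder_haps=implanted,
    )
    return data, truth


# ---------------------------------------------------------------------------
# phenotypes and study ascertainment
# ---------------------------------------------------------------------------

def assign_phenotypes(
    data: GenotypeData,
    truth: SimTruth,
    risk: RiskHaplotype,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
) -> GenotypeData:
    """Penetrance-model phenotypes plus exact case/control ascertainment.

    Every cohort animal becomes affected with probability
    ``penetrance_carrier`` or ``penetrance_noncarrier`` by its true carrier
    status; exactly ``n_cases`` affected and ``n_controls`` unaffected
    animals are then sampled and returned as a new dataset (others are
    dropped, emulating matched-sample ascertainment from a larger herd).
    """
    rng = np.random.default_rng(seed)
    cohort = data.sample_ids
    info = truth.individuals.set_index("iid")
    carrier = info.loc[cohort, "carrier"].to_numpy()
    pen = np.where(carrier, risk.penetrance_carrier, risk.penetrance_noncarrier)
    affected = rng.random(len(cohort)) < pen
    n_aff = int(affected.sum())
    n_un = len(cohort) - n_aff
    if n_aff < n_cases or n_un < n_controls:
        raise ValueError(
            f"infeasible ascertainment: {n_aff} affected / {n_un} unaffected "
            f"available, {n_cases} cases / {n_controls} controls requested"
        )
    case_idx = rng.choice(np.flatnonzero(affected), size=n_cases, replace=False)
    control_idx = rng.choice(np.flatnonzero(~affected), size=n_controls, replace=False)
    keep = np.sort(np.concatenate([case_idx, control_idx]))
    out = data.subset(sample_idx=keep)
    pheno = np.where(np.isin(keep, case_idx), PHENO_CASE, PHENO_CONTROL)
    out.samples["phenotype"] = pheno
    return out


def simulate_case_control_study(
    config: SimConfig | None = None, seed: int | None = None
):
    """One ascertained case/control study: returns (GenotypeData, SimTruth).

    Convenience wrapper: gene-drops the population, applies the penetrance
    model of ``config.risk`` and ascertains ``config.n_cases`` /
    ``config.n_controls`` animals.
    """
    cfg = config or SimConfig()
    if cfg.risk is None:
        raise ValueError("config.risk is required to assign phenotypes")
    base_seed = cfg.seed if seed is None else seed
    # Ascertained designs condition on the herd containing enough affected
    # and unaffected animals; rejection-sample whole populations until the
    # requested margins are feasible.
    last_err: Exception | None = None
    for attempt in range(25):
        s = (base_seed + 7919 * attempt) % (2**31 - 1)
        data, truth = simulate_population(cfg, seed=s)
        try:
            study = assign_phenotypes(
                data, truth, cfg.risk, cfg.n_cases, cfg.n_controls, seed=s + 1
            )
            return study, truth
        except ValueError as err:
            last_err = err
    raise ValueError(
        f"could not ascertain {cfg.n_cases}/{cfg.n_controls} in 25 attempts; "
        f"last: {last_err}"
    )


def write_fixture(data: GenotypeData, truth: SimTruth, out_dir) -> dict:
    """Write the simulated study as PED/MAP plus truth TSVs.

    Returns the paths written: ped, map, truth (per-individual table with
    pedigree F, realized autozygosity and carrier status).
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    ped = os.path.join(out_dir, "fixture.ped")
    map_ = os.path.join(out_dir, "fixture.map")
    write_ped_map(data, ped, map_)
    truth_path = os.path.join(out_dir, "fixture.truth.tsv")
    truth.individuals.to_csv(truth_path, sep="\t", index=False)
    return {"ped": ped, "map": map_, "truth": truth_path}


def simulate_unrelated_panel(
    n_samples: int = 53,
    n_cases: int = 35,
    n_markers: int = 2000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_chromosomes: int = 18,
    chrom_length_bp: int = 130_000_000,
    seed: int = 0,
) -> GenotypeData:
    """Unstructured null panel: unrelated samples, independent HWE markers,
    case/control labels assigned at random (no true associations).

    Used for calibration checks (genomic inflation, allelic-test type-I
    error).
    """
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=n_markers)
    calls = (
        (rng.random((n_samples, n_markers)) < maf).astype(np.int8)
        + (rng.random((n_samples, n_markers)) < maf).astype(np.int8)
    )
    per_chrom = int(np.ceil(n_markers / n_chromosomes))
    chroms = []
    bps = []
    for j in range(n_markers):
        c = j // per_chrom + 1
        k = j % per_chrom
        chroms.append(str(min(c, n_chromosomes)))
        bps.append((k + 1) * max(1, chrom_length_bp // (per_chrom + 1)))
    markers = pd.DataFrame(
        {
            "chrom": chroms,
            "snp": [f"NULL{j+1}" for j in range(n_markers)],
            "cm": 0.0,
            "bp": bps,
            "a1": "A",
            "a2": "G",
        }
    )
    pheno = np.full(n_samples, PHENO_CONTROL)
    pheno[rng.choice(n_samples, size=n_cases, replace=False)] = PHENO_CASE
    samples = pd.DataFrame(
        {
            "fid": "NULL",
            "iid": [f"S{i+1:03d}" for i in range(n_samples)],
            "father": "0",
            "mother": "0",
            "sex": 1,
            "phenotype": pheno,
        }
    )
    return sort_markers(GenotypeData(calls=calls, markers=markers, samples=samples))


def cousin_mating_population(
    n_offspring: int = 4,
    n_chromosomes: int = 10,
    markers_per_chrom: int = 2000,
    chrom_length_bp: int = 100_000_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
):
    """Offspring of a first-cousin mating (pedigree F = 1/16) on a dense map.

    Builds the minimal loop — one grandparental couple, two sib parents
    married out to unrelated founders, their children (first cousins) mated
    — and returns (GenotypeData of the offspring, SimTruth) for
    inbreeding-recovery checks.
    """
    cfg = SimConfig(
        n_autosomes=n_chromosomes,
        markers_per_autosome=markers_per_chrom,
        x_markers=0,
        autosome_length_bp=chrom_length_bp,
        founder_maf_range=maf_range,
        n_founders=4,
        generation_sizes=(),
        risk=None,
        missing_rate=0.0,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    chroms = cfg.chrom_labels()

    # reuse the generator's machinery with an explicit pedigree
    data, truth = simulate_population(cfg, seed=seed)  # founders only cohort
    haplotypes = truth.haplotypes
    ped_rows = list(
        truth.individuals[["iid", "father", "mother", "generation"]].itertuples(index=False, name=None)
    )

    def drop(iid, sire, dam, gen):
        ped_rows.append((iid, sire, dam, gen))
        haplotypes[iid] = {}
        for chrom in chroms:
            length = cfg.chrom_length(chrom)
            hs = haplotypes[sire][chrom]
            hd = haplotypes[dam][chrom]
            haplotypes[iid][chrom] = (
                _recombine(hs[0], hs[1], length, cfg.cm_per_mb, rng),
                _recombine(hd[0], hd[1], length, cfg.cm_per_mb, rng),
            )

    # F001 x F002 -> sibs S1, S2; married out to F003 / F004 -> cousins C1, C2
    drop("S1", "F001", "F002", 1)
    drop("S2", "F001", "F002", 1)
    drop("C1", "S1", "F003", 2)
    drop("C2", "S2", "F004", 2)
    offspring = [f"O{k+1:02d}" for k in range(n_offspring)]
    for o in offspring:
        drop(o, "C1", "C2", 3)

    individuals = pd.DataFrame(ped_rows, columns=["iid", "father", "mother", "generation"])
    individuals["pedigree_f"] = _pedigree_f(individuals)
    auto_total = sum(cfg.chrom_length(c) for c in chroms)
    individuals["autozygosity"] = [
        sum(
            _autozygosity(haplotypes[i][c], cfg.chrom_length(c)) * cfg.chrom_length(c)
            for c in chroms
        )
        / auto_total
        for i in individuals["iid"]
    ]
    individuals["carrier"] = False
    individuals["n_implant_copies"] = 0

    # paint the offspring genotypes using the recorded founder allele panel
    bp_by_chrom = {c: data.markers.loc[data.markers["chrom"] == c, "bp"].to_numpy() for c in chroms}
    calls = np.zeros((n_offspring, data.n_markers), dtype=np.int8)
    marker_order = {(r.chrom, r.bp): k for k, r in enumerate(data.markers.itertuples(index=False))}
    for i, iid in enumerate(offspring):
        for chrom in chroms:
            bp = bp_by_chrom[chrom]
            h0, h1 = haplotypes[iid][chrom]
            falle = truth.founder_alleles[chrom]
            a = _paint(h0, falle, bp) + _paint(h1, falle, bp)
            cols = [marker_order[(chrom, int(p))] for p in bp]
            calls[i, cols] = a
    samples = pd.DataFrame(
        {
            "fid": "COUSIN",
            "iid": offspring,
            "father": "C1",
            "mother": "C2",
            "sex": 1,
            "phenotype": PHENO_MISSING,
        }
    )
    out = GenotypeData(calls=calls, markers=data.markers.copy(), samples=samples)
    return out, SimTruth(
        individuals=individuals,
        haplotypes=haplotypes,
        founder_alleles=truth.founder_alleles,
    )
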