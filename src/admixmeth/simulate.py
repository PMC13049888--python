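"""Synthetic admixed cohorts with known ground truth.

Emulates the study design this package targets: two parental taxa
(labelled "yellow" and "anubis") whose shared variants have drifted apart
(Balding-Nichols model), a hybrid population whose chromosomes are
mosaics of local-ancestry tracts, CpG methylation driven by per-allele
methylation probabilities at linked meQTL (including CpG-disrupting
alleles), RRBS-like overdispersed read counts with read-level allele
assignment for SNP-CpG pairs co-observed on reads, and a
reporter-assay (DNA/RNA replicate) experiment with a subset of active
and methylation-dependent windows.

Every operation is deterministic given its seed; the cohort-level
orchestrator derives independent substreams per component from the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import AncestryPanel, MethCountMatrix, ReporterCounts
from .exceptions import AlignmentError, ParameterError

__all__ = [
    "SimConfig",
    "ReporterConfig",
    "ParentalFrequencies",
    "GroundTruth",
    "Genotypes",
    "SimulatedCohort",
    "simulate_parental_frequencies",
    "simulate_ancestry",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_reporter",
    "simulate_cohort",
    "simulate_parental_cohort",
]

AIM_THRESHOLD = 0.2  # minimum parental allele-frequency difference for an AIM
READ_LENGTH = 100  # bp; sets P(read covers both SNP and CpG) = 1 - d/100
_DISRUPTED_METH = 0.01  # methylation probability on a CpG-disrupting allele


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic admixed cohort.

    Defaults mirror the study system this package emulates: a cohort of
    256 individuals from a hybrid population with mean anubis admixture
    fraction 0.37, parental taxa at Balding-Nichols divergence F = 0.28
    (the middle of reported F_ST estimates of 0.23-0.33 between yellow
    and anubis baboons), RRBS-like coverage around 20 reads per CpG, and
    megabase-scale ancestry tracts.
    """

    n_individuals: int = 256
    n_chromosomes: int = 1
    chrom_length: int = 20_000_000
    n_snps: int = 1000
    n_cpgs: int = 1000
    divergence_F: float = 0.28
    admix_alpha: float = 0.37
    mean_tract_bp: float = 1_000_000.0
    mean_coverage: float = 20.0
    coverage_shape: float = 5.0  # negative-binomial shape; RRBS coverage is overdispersed
    bb_dispersion: float = 0.05
    frac_meqtl: float = 0.5
    frac_disrupted: float = 0.1
    effect_sd_logit: float = 1.5
    seed: int = 0

    def __post_init__(self):
        for name in ("admix_alpha", "frac_meqtl", "frac_disrupted"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.divergence_F < 1.0) or not np.isfinite(self.divergence_F):
            raise ParameterError(f"divergence_F must be in (0, 1), got {self.divergence_F}")
        if self.chrom_length <= self.mean_tract_bp:
            raise ParameterError("chrom_length must exceed mean_tract_bp")
        if self.mean_coverage <= 0:
            raise ParameterError("mean_coverage must be positive")
        if self.bb_dispersion < 0:
            raise ParameterError("bb_dispersion must be >= 0")


@dataclass
class ParentalFrequencies:
    """Per-SNP allele frequencies in the two parental taxa."""

    p_yellow: np.ndarray
    p_anubis: np.ndarray

    @property
    def is_aim(self):
        """Ancestry-informative markers: parental frequencies differ by >= 0.2."""
        return np.abs(self.p_anubis - self.p_yellow) >= AIM_THRESHOLD

    @property
    def n_snps(self):
        return self.p_yellow.shape[0]


@dataclass
class GroundTruth:
    """Per-CpG generating parameters (the oracle for every downstream test).

    ``linked_snp`` is the index of the causal SNP, or -1 for CpGs with no
    meQTL. ``true_delta`` is the per-allele effect on the proportion
    scale (m_alt - m_ref) and ``true_ancestry_effect`` its composition
    with the parental frequency difference, delta * (p_anubis - p_yellow).
    """

    baseline_logit: np.ndarray
    m_ref: np.ndarray
    m_alt: np.ndarray
    is_disrupted: np.ndarray
    linked_snp: np.ndarray
    true_ancestry_effect: np.ndarray

    @property
    def true_delta(self):
        return self.m_alt - self.m_ref

    @property
    def has_meqtl(self):
        return self.linked_snp >= 0


@dataclass
class Genotypes:
    """Phased genotypes at simulated SNPs (alt-allele dosage coding)."""

    chrom: np.ndarray
    pos: np.ndarray
    individuals: list
    hap_alleles: np.ndarray  # (n_ind, 2, n_snps), 1 = alt allele
    ref: np.ndarray = None
    alt: np.ndarray = None

    def __post_init__(self):
        if self.ref is None:
            self.ref = np.full(self.pos.shape[0], "A")
        if self.alt is None:
            self.alt = np.full(self.pos.shape[0], "T")

    @property
    def dosage(self):
        return self.hap_alleles.sum(axis=1)

    @property
    def n_snps(self):
        return self.pos.shape[0]


def simulate_parental_frequencies(n_snps, divergence_F, seed):
    """Draw parental allele frequencies under the Balding-Nichols model.

    Each SNP gets an ancestral frequency p ~ Uniform(0.05, 0.95), then
    taxon frequencies drawn independently from
    Beta(p (1-F)/F, (1-p) (1-F)/F), whose variance around p is
    F p (1-p) -- i.e. F plays the role of F_ST between the taxa.
    """
    if not np.isfinite(divergence_F) or not (0.0 < divergence_F < 1.0):
        raise ParameterError(f"divergence_F must be in (0, 1), got {divergence_F}")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_snps)
    c = (1.0 - divergence_F) / divergence_F
    p_yellow = rng.beta(p * c, (1.0 - p) * c)
    p_anubis = rng.beta(p * c, (1.0 - p) * c)
    return ParentalFrequencies(p_yellow=p_yellow, p_anubis=p_anubis)


def _simulate_haplotype_tracts(rng, chrom_length, alpha, mean_tract_bp):
    """One haplotype's ancestry segments: two-state Markov process.

    Switch rates are chosen so the stationary anubis probability is
    ``alpha`` and the (count-weighted) mean segment length is
    ``mean_tract_bp``: the yellow->anubis rate is alpha*c and the
    anubis->yellow rate (1-alpha)*c with c = 1 / (2 alpha (1-alpha) T).

    Returns (breakpoints, states): segment i spans
    [breakpoints[i], breakpoints[i+1]) with ancestry states[i] (1=anubis).
    """
    if alpha <= 0.0 or alpha >= 1.0:
        state = 1 if alpha >= 1.0 else 0
        return np.array([0, chrom_length]), np.array([state], dtype=np.int8)
    c = 1.0 / (2.0 * alpha * (1.0 - alpha) * mean_tract_bp)
    rate = {0: alpha * c, 1: (1.0 - alpha) * c}
    state = int(rng.random() < alpha)
    pos, bps, states = 0.0, [0], []
    while pos < chrom_length:
        seg = rng.exponential(1.0 / rate[state])
        pos = min(pos + seg, chrom_length)
        bps.append(int(round(pos)))
        states.append(state)
        state = 1 - state
    bps = np.array(bps, dtype=np.int64)
    keep = np.diff(bps) > 0
    return np.concatenate([[0], bps[1:][keep]]), np.array(states, dtype=np.int8)[keep]


def simulate_ancestry(config, chrom=None, pos=None):
    """Mosaic local-ancestry tracts and dosages for a hybrid cohort.

    Parameters
    ----------
    config : SimConfig
    chrom, pos : arrays, optional
        Loci at which to record per-individual dosage. By default
        ``config.n_snps`` uniformly placed loci per chromosome.

    Returns
    -------
    AncestryPanel
        With per-haplotype states stashed as ``panel.hap_state`` of shape
        (n_individuals, 2, n_loci) and a ``tracts`` BED-like frame.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    if pos is None:
        per = config.n_snps // config.n_chromosomes
        chrom, pos = _uniform_positions(rng, chroms, per, config.chrom_length)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    n_ind, n_loci = config.n_individuals, pos.shape[0]
    hap_state = np.zeros((n_ind, 2, n_loci), dtype=np.int8)
    tract_rows = []
    for i in range(n_ind):
        for h in range(2):
            for c in chroms:
                on_c = chrom == c
                bps, states = _simulate_haplotype_tracts(
                    rng, config.chrom_length, config.admix_alpha, config.mean_tract_bp
                )
                seg = np.searchsorted(bps, pos[on_c], side="right") - 1
                seg = np.clip(seg, 0, len(states) - 1)
                hap_state[i, h, on_c] = states[seg]
                for j in range(len(states)):
                    tract_rows.append((c, bps[j], bps[j + 1], i, h, int(states[j])))
    tracts = pd.DataFrame(
        tract_rows, columns=["chrom", "start", "end", "individual", "haplotype", "state"]
    )
    dosage = hap_state.sum(axis=1, dtype=np.int8)
    panel = AncestryPanel(
        chrom=chrom,
        pos=pos,
        individuals=[f"ind{i}" for i in range(n_ind)],
        dosage=dosage,
        tracts=tracts,
    )
    panel.hap_state = hap_state
    return panel


def _uniform_positions(rng, chroms, n_per_chrom, length):
    cs, ps = [], []
    for c in chroms:
        draw = np.unique(rng.integers(200, length - 200, size=int(n_per_chrom * 2.2)))
        rng.shuffle(draw)
        take = np.sort(draw[:n_per_chrom])
        ps.append(take)
        cs.append(np.full(take.shape[0], c))
    return np.concatenate(cs), np.concatenate(ps)


def simulate_genotypes(panel, freqs, seed):
    """Draw phased genotypes from each haplotype's local-ancestry frequency.

    The allele on haplotype h at SNP j is Bernoulli with the anubis
    parental frequency if the haplotype's local ancestry there is anubis,
    and the yellow frequency otherwise. Genotype dosage is the sum of the
    two haplotype alleles (alt-allele count).
    """
    if freqs.n_snps != panel.n_loci:
        raise AlignmentError(
            f"panel has {panel.n_loci} loci but frequencies cover {freqs.n_snps} SNPs"
        )
    if not hasattr(panel, "hap_state"):
        raise AlignmentError("panel lacks per-haplotype states (use simulate_ancestry)")
    rng = np.random.default_rng(seed)
    p = np.where(panel.hap_state == 1, freqs.p_anubis, freqs.p_yellow)
    hap_alleles = (rng.random(p.shape) < p).astype(np.int8)
    return Genotypes(
        chrom=panel.chrom,
        pos=panel.pos,
        individuals=list(panel.individuals),
        hap_alleles=hap_alleles,
    )


def _sample_truth(rng, config, freqs, n_cpgs, linked_snp):
    """Per-CpG baselines and per-allele methylation probabilities."""
    baseline = rng.uniform(0.10, 0.90, size=n_cpgs)
    baseline_logit = logit(baseline)
    m_ref = baseline.copy()
    m_alt = baseline.copy()
    has = linked_snp >= 0
    effects = rng.normal(0.0, config.effect_sd_logit, size=n_cpgs)
    m_alt[has] = expit(baseline_logit[has] + effects[has])
    is_disrupted = np.zeros(n_cpgs, dtype=bool)
    n_linked = int(has.sum())
    if n_linked:
        idx = np.where(has)[0]
        n_dis = int(round(config.frac_disrupted * n_linked))
        dis = rng.choice(idx, size=n_dis, replace=False)
        is_disrupted[dis] = True
        m_alt[dis] = _DISRUPTED_METH
    dp = np.zeros(n_cpgs)
    dp[has] = freqs.p_anubis[linked_snp[has]] - freqs.p_yellow[linked_snp[has]]
    true_effect = (m_alt - m_ref) * dp
    return GroundTruth(
        baseline_logit=baseline_logit,
        m_ref=m_ref,
        m_alt=m_alt,
        is_disrupted=is_disrupted,
        linked_snp=linked_snp,
        true_ancestry_effect=true_effect,
    )


def simulate_methylation(genotypes, truth, config, cpg_chrom, cpg_pos, pair_distance, seed):
    """RRBS-like methylation counts with read-level allele assignment.

    Per individual per CpG: coverage is negative-binomial with mean
    ``config.mean_coverage``; each read picks one of the individual's two
    haplotypes uniformly; its methylation state is Bernoulli with that
    haplotype allele's methylation probability, perturbed by a
    beta-distributed individual x haplotype effect with intraclass
    correlation ``config.bb_dispersion`` (0 = pure binomial).

    For CpGs with a linked SNP within 100 bp, a read covers the SNP (and
    is therefore allele-assignable) with probability 1 - distance/100;
    assignable reads yield per-heterozygote allele-specific counts.

    Returns
    -------
    (MethCountMatrix, pandas.DataFrame)
        The count matrix over all reads, and a long-format table of
        pair-level counts with one row per (CpG with linked SNP,
        individual): total/meth, the non-assignable remainder
        (``total_excl``/``meth_excl``) and, for heterozygotes,
        allele-specific assignable counts
        (``meth_ref``/``total_ref``/``meth_alt``/``total_alt``).
    """
    rng = np.random.default_rng(seed)
    n_cpgs = truth.baseline_logit.shape[0]
    n_ind = len(genotypes.individuals)
    phi = config.bb_dispersion

    r = config.coverage_shape
    coverage = rng.negative_binomial(r, r / (r + config.mean_coverage), size=(n_cpgs, n_ind))
    if not coverage.any():
        import warnings

        warnings.warn("zero coverage everywhere: degenerate methylation matrix")
    n_hap1 = rng.binomial(coverage, 0.5)
    n_hap = np.stack([n_hap1, coverage - n_hap1], axis=2)  # (cpg, ind, hap)

    # per-haplotype methylation probability at each CpG
    m_hap = np.broadcast_to(
        expit(truth.baseline_logit)[:, None, None], (n_cpgs, n_ind, 2)
    ).copy()
    has = truth.has_meqtl
    if has.any():
        snp_of = truth.linked_snp[has]
        alle = genotypes.hap_alleles[:, :, snp_of]  # (ind, hap, linked-cpg)
        alle = np.moveaxis(alle, 2, 0)  # (linked-cpg, ind, hap)
        m_hap[has] = np.where(alle == 1, truth.m_alt[has, None, None], truth.m_ref[has, None, None])

    if phi > 0:
        interior = (m_hap > 1e-9) & (m_hap < 1.0 - 1e-9)
        s = (1.0 - phi) / phi
        a = np.clip(m_hap, 1e-9, 1 - 1e-9) * s
        b = (1.0 - np.clip(m_hap, 1e-9, 1 - 1e-9)) * s
        draw = rng.beta(a, b)
        p_hap = np.where(interior, draw, m_hap)
    else:
        p_hap = m_hap
    k_hap = rng.binomial(n_hap, p_hap)

    counts = MethCountMatrix(
        chrom=cpg_chrom,
        pos=cpg_pos,
        individuals=list(genotypes.individuals),
        meth=k_hap.sum(axis=2),
        total=n_hap.sum(axis=2),
    )

    # allele-assignable reads at linked CpGs
    rows = []
    linked = np.where(has)[0]
    for j in linked:
        snp = truth.linked_snp[j]
        d = pair_distance[j]
        p_assign = max(0.0, 1.0 - d / READ_LENGTH)
        n_as = rng.binomial(n_hap[j], p_assign)  # (ind, hap)
        # methylated reads among the assignable subset: hypergeometric draw
        # (guard the degenerate zero-read cells, then zero them back out)
        ngood = k_hap[j]
        nbad = n_hap[j] - k_hap[j] + (n_hap[j] == 0)
        k_as = rng.hypergeometric(ngood, nbad, np.maximum(n_as, 1))
        k_as = np.where(n_as > 0, k_as, 0)
        dosage = genotypes.dosage[:, snp]
        hap_allele = genotypes.hap_alleles[:, :, snp]  # (ind, hap)
        is_het = dosage == 1
        total_ref = np.where(is_het, (n_as * (hap_allele == 0)).sum(axis=1), 0)
        meth_ref = np.where(is_het, (k_as * (hap_allele == 0)).sum(axis=1), 0)
        total_alt = np.where(is_het, (n_as * (hap_allele == 1)).sum(axis=1), 0)
        meth_alt = np.where(is_het, (k_as * (hap_allele == 1)).sum(axis=1), 0)
        total_all = n_hap[j].sum(axis=1)
        meth_all = k_hap[j].sum(axis=1)
        # heterozygotes contribute assignable reads via the allele-specific
        # component; everything else stays in the individual-level counts
        total_excl = np.where(is_het, total_all - total_ref - total_alt, total_all)
        meth_excl = np.where(is_het, meth_all - meth_ref - meth_alt, meth_all)
        for i in range(n_ind):
            rows.append(
                (
                    j,
                    snp,
                    genotypes.individuals[i],
                    int(dosage[i]),
                    int(meth_all[i]),
                    int(total_all[i]),
                    int(meth_excl[i]),
                    int(total_excl[i]),
                    int(meth_ref[i]),
                    int(total_ref[i]),
                    int(meth_alt[i]),
                    int(total_alt[i]),
                )
            )
    pair_counts = pd.DataFrame(
        rows,
        columns=[
            "cpg_index",
            "snp_index",
            "individual",
            "genotype",
            "meth",
            "total",
            "meth_excl",
            "total_excl",
            "meth_ref",
            "total_ref",
            "meth_alt",
            "total_alt",
        ],
    )
    return counts, pair_counts


@dataclass
class SimulatedCohort:
    """Everything the downstream stages need, plus the generating truth."""

    config: SimConfig
    freqs: ParentalFrequencies
    panel: AncestryPanel  # at CpG positions (for the ancestry scan)
    snp_panel: AncestryPanel  # at SNP positions
    genotypes: Genotypes
    truth: GroundTruth
    counts: MethCountMatrix
    pair_counts: pd.DataFrame
    pairs: pd.DataFrame  # cpg_index, snp_index, distance, disrupted


def simulate_cohort(config):
    """Generate a complete synthetic cohort from one config.

    Lays out SNPs uniformly along each chromosome, links a fraction
    ``frac_meqtl`` of CpGs to a SNP within 100 bp (a fraction
    ``frac_disrupted`` of those overlapping the CpG dinucleotide itself),
    then runs ancestry, genotype and methylation simulation with
    independent substreams of ``config.seed``.
    """
    root = np.random.SeedSequence(int(config.seed))
    s_pos, s_freq, s_geno, s_meth = [int(s.generate_state(1)[0]) % (2**31) for s in root.spawn(4)]
    rng = np.random.default_rng(s_pos)

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    snp_chrom, snp_pos = _uniform_positions(
        rng, chroms, config.n_snps // config.n_chromosomes, config.chrom_length
    )
    n_snps = snp_pos.shape[0]

    n_cpgs = config.n_cpgs
    n_linked = int(round(config.frac_meqtl * n_cpgs))
    linked_snps = rng.choice(n_snps, size=n_linked, replace=False)
    n_dis = int(round(config.frac_disrupted * n_linked))
    offsets = np.empty(n_linked, dtype=np.int64)
    offsets[:n_dis] = rng.integers(0, 2, size=n_dis) - 1  # SNP at CpG pos or pos+1
    offsets[n_dis:] = rng.integers(2, READ_LENGTH + 1, size=n_linked - n_dis) * rng.choice(
        [-1, 1], size=n_linked - n_dis
    )
    cpg_pos_linked = snp_pos[linked_snps] - offsets
    cpg_chrom_linked = snp_chrom[linked_snps]

    n_free = n_cpgs - n_linked
    free_chrom, free_pos = _uniform_positions(
        rng, chroms, int(np.ceil(n_free / config.n_chromosomes)), config.chrom_length
    )
    free_chrom, free_pos = free_chrom[:n_free], free_pos[:n_free]

    cpg_chrom = np.concatenate([cpg_chrom_linked, free_chrom])
    cpg_pos = np.concatenate([cpg_pos_linked, free_pos])
    linked_snp = np.concatenate([linked_snps, np.full(n_free, -1)]).astype(np.int64)
    distance = np.concatenate([np.abs(offsets), np.zeros(n_free, dtype=np.int64)])

    # sort CpGs by position within chromosome, dropping rare position clashes
    order = np.lexsort((cpg_pos, cpg_chrom))
    cpg_chrom, cpg_pos = cpg_chrom[order], cpg_pos[order]
    linked_snp, distance = linked_snp[order], distance[order]
    keep = np.ones(cpg_pos.shape[0], dtype=bool)
    keep[1:] = ~((np.diff(cpg_pos) == 0) & (cpg_chrom[1:] == cpg_chrom[:-1]))
    cpg_chrom, cpg_pos = cpg_chrom[keep], cpg_pos[keep]
    linked_snp, distance = linked_snp[keep], distance[keep]

    # one ancestry realization over the union of SNP and CpG loci
    union_chrom = np.concatenate([snp_chrom, cpg_chrom])
    union_pos = np.concatenate([snp_pos, cpg_pos])
    u_order = np.lexsort((union_pos, union_chrom))
    panel_all = simulate_ancestry(config, union_chrom[u_order], union_pos[u_order])
    back = np.empty_like(u_order)
    back[u_order] = np.arange(u_order.shape[0])
    snp_sel, cpg_sel = back[: snp_pos.shape[0]], back[snp_pos.shape[0]:]

    snp_panel = panel_all.subset_loci(snp_sel)
    snp_panel.hap_state = panel_all.hap_state[:, :, snp_sel]
    cpg_panel = panel_all.subset_loci(cpg_sel)
    cpg_panel.hap_state = panel_all.hap_state[:, :, cpg_sel]

    freqs = simulate_parental_frequencies(n_snps, config.divergence_F, s_freq)
    genotypes = simulate_genotypes(snp_panel, freqs, s_geno)

    rng_truth = np.random.default_rng(s_pos + 1)
    truth = _sample_truth(rng_truth, config, freqs, cpg_pos.shape[0], linked_snp)
    counts, pair_counts = simulate_methylation(
        genotypes, truth, config, cpg_chrom, cpg_pos, distance, s_meth
    )
    pairs = pd.DataFrame(
        {
            "cpg_index": np.where(linked_snp >= 0)[0],
            "snp_index": linked_snp[linked_snp >= 0],
            "distance": distance[linked_snp >= 0],
            "disrupted": distance[linked_snp >= 0] <= 1,
        }
    )
    return SimulatedCohort(
        config=config,
        freqs=freqs,
        panel=cpg_panel,
        snp_panel=snp_panel,
        genotypes=genotypes,
        truth=truth,
        counts=counts,
        pair_counts=pair_counts,
        pairs=pairs,
    )


def simulate_parental_cohort(cohort, n_yellow, n_anubis, seed, mean_coverage=None):
    """Unadmixed reference samples sharing the hybrid cohort's truth.

    Draws ``n_yellow`` individuals with pure yellow ancestry and
    ``n_anubis`` with pure anubis ancestry, genotypes from the
    corresponding parental frequencies, and methylation counts from the
    same per-allele ground truth as the hybrid cohort -- the setup for a
    between-taxon differential methylation analysis whose results should
    be recapitulated by within-hybrid ancestry effects.

    Returns (counts_yellow, counts_anubis) as MethCountMatrix objects
    over the cohort's CpG sites.
    """
    cfg = cohort.config
    root = np.random.SeedSequence([int(seed), 77])
    out = []
    for label, n_taxon, p in (
        ("Y", n_yellow, cohort.freqs.p_yellow),
        ("A", n_anubis, cohort.freqs.p_anubis),
    ):
        rng = np.random.default_rng(root.spawn(1)[0])
        hap = (rng.random((n_taxon, 2, cohort.freqs.n_snps)) < p).astype(np.int8)
        geno = Genotypes(
            chrom=cohort.genotypes.chrom,
            pos=cohort.genotypes.pos,
            individuals=[f"{label}{i}" for i in range(n_taxon)],
            hap_alleles=hap,
        )
        cov = mean_coverage if mean_coverage is not None else cfg.mean_coverage
        cfg_taxon = SimConfig(
            n_individuals=n_taxon,
            n_chromosomes=cfg.n_chromosomes,
            chrom_length=cfg.chrom_length,
            n_snps=cfg.n_snps,
            n_cpgs=cfg.n_cpgs,
            divergence_F=cfg.divergence_F,
            admix_alpha=0.0 if label == "Y" else 1.0,
            mean_tract_bp=cfg.mean_tract_bp,
            mean_coverage=cov,
            coverage_shape=cfg.coverage_shape,
            bb_dispersion=cfg.bb_dispersion,
            frac_meqtl=cfg.frac_meqtl,
            frac_disrupted=cfg.frac_disrupted,
            effect_sd_logit=cfg.effect_sd_logit,
            seed=cfg.seed,
        )
        dist = np.zeros(cohort.counts.n_sites, dtype=np.int64)
        counts, _ = simulate_methylation(
            geno, cohort.truth, cfg_taxon, cohort.counts.chrom, cohort.counts.pos,
            dist, seed=int(root.generate_state(1)[0] % (2**31)) + (0 if label == "Y" else 1),
        )
        out.append(counts)
    return tuple(out)


# ---------------------------------------------------------------------------
# reporter assay


@dataclass(frozen=True)
class ReporterConfig:
    """Knobs of the synthetic reporter-assay (DNA/RNA replicate) experiment.

    ``frac_unmeth_more_active`` sets which fraction of
    methylation-dependent windows are more active in the unmethylated
    condition (default 0.87, the study's reported split). Multipliers of
    4-8x over the baseline RNA/DNA ratio are "strong" effects that a
    six-replicate design can detect.
    """

    n_windows: int = 5000
    n_replicates: int = 6
    frac_active: float = 0.05
    frac_meth_dependent: float = 0.03
    frac_unmeth_more_active: float = 0.87
    mean_dna: float = 50.0
    baseline_rna_ratio: float = 0.3
    activity_multiplier: tuple = (4.0, 8.0)
    nb_shape: float = 10.0
    library_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.frac_meth_dependent > self.frac_active:
            raise ParameterError("frac_meth_dependent cannot exceed frac_active")
        for name in ("frac_active", "frac_meth_dependent", "frac_unmeth_more_active"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1]")


def simulate_reporter(config):
    """Reporter DNA/RNA replicate counts with known activity labels.

    DNA counts are negative-binomial around a lognormal per-window
    propensity times a per-replicate library factor. RNA expectation is
    the DNA propensity times ``baseline_rna_ratio`` (most windows emit
    less RNA than DNA input) times an activity multiplier: 1 for inactive
    windows, a strong constant for active windows, condition-specific for
    methylation-dependent windows (active in one condition only).

    Returns a :class:`ReporterCounts` whose ``truth`` frame carries
    ``is_active``, ``is_meth_dependent`` and ``more_active_unmeth``.
    """
    rng = np.random.default_rng(config.seed)
    nw, nr = config.n_windows, config.n_replicates

    n_active = int(round(config.frac_active * nw))
    n_dep = int(round(config.frac_meth_dependent * nw))
    is_active = np.zeros(nw, dtype=bool)
    is_active[:n_active] = True
    is_dep = np.zeros(nw, dtype=bool)
    is_dep[:n_dep] = True
    more_unmeth = np.zeros(nw, dtype=bool)
    n_unmeth_pref = int(round(config.frac_unmeth_more_active * n_dep))
    more_unmeth[:n_unmeth_pref] = True
    perm = rng.permutation(nw)
    is_active, is_dep, more_unmeth = is_active[perm], is_dep[perm], more_unmeth[perm]
    more_unmeth &= is_dep

    lam = np.exp(rng.normal(np.log(config.mean_dna), 0.7, size=nw))
    act = rng.uniform(*config.activity_multiplier, size=nw)
    always = is_active & ~is_dep
    mult = {
        "methylated": np.where(always | (is_dep & ~more_unmeth), act, 1.0),
        "unmethylated": np.where(always | (is_dep & more_unmeth), act, 1.0),
    }

    sample_rows, count_cols = [], []
    r = config.nb_shape
    for cond in ("methylated", "unmethylated"):
        for assay in ("DNA", "RNA"):
            for rep in range(nr):
                lib = np.exp(rng.normal(0.0, config.library_sd))
                mean = lam * lib
                if assay == "RNA":
                    mean = mean * config.baseline_rna_ratio * mult[cond]
                count_cols.append(rng.negative_binomial(r, r / (r + mean)))
                sample_rows.append((assay, cond, rep))
    samples = pd.DataFrame(sample_rows, columns=["assay", "condition", "replicate"])
    truth = pd.DataFrame(
        {
            "is_active": is_active,
            "is_meth_dependent": is_dep,
            "more_active_unmeth": more_unmeth,
            "multiplier_methylated": mult["methylated"],
            "multiplier_unmethylated": mult["unmethylated"],
        }
    )
    return ReporterCounts(
        window_id=np.array([f"w{i}" for i in range(nw)]),
        chrom=np.full(nw, "chr1"),
        start=np.arange(nw, dtype=np.int64) * 500,
        end=np.arange(1, nw + 1, dtype=np.int64) * 500,
        samples=samples,
        counts=np.column_stack(count_cols),
        truth=truth,
    )
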