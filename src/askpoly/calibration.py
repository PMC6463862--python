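"""Self-calibration experiments: estimator checks on synthetic data.

These routines exercise the whole pipeline against its own generators'
ground truth — neutral-coalescent calibration of pi / theta_W / Tajima's D,
parameter recovery and error rates of the codon-model neutrality test,
assembly round trips, and recovery of planted structure by the window and
clustering machinery.  They are what the acceptance script and the
acceptance tests run; problem sizes are the library defaults below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import assemble_alignment, diff_sequences
from .cluster import cluster_statistic_matrix
from .divergence import (NEUTRALITY_LRT_THRESHOLD, build_codon_alignment,
                         evaluate_pair_neutrality)
from .popgen import nucleotide_diversity, segregating_sites, tajimas_d, watterson_theta
from .simulate import simulate_coalescent_snps, simulate_structured_region
from .windows import compare_window_profiles


@dataclass
class NeutralCalibration:
    theta_true: float
    mean_pi_site: float
    se_pi_site: float
    mean_theta_site: float
    se_theta_site: float
    mean_tajima_d: float
    n_replicates: int

    @property
    def pi_z(self) -> float:
        return (self.mean_pi_site - self.theta_true) / self.se_pi_site

    @property
    def theta_z(self) -> float:
        return (self.mean_theta_site - self.theta_true) / self.se_theta_site


def neutral_coalescent_calibration(n: int = 20, L: int = 1000,
                                   theta_site: float = 0.01,
                                   n_replicates: int = 2000,
                                   seed: int = 0) -> NeutralCalibration:
    """Means of pi_site, theta_site and Tajima's D over neutral replicates.

    Defaults put theta*L = 10 per locus; under neutrality both estimators
    are unbiased for theta_site and D has mean near zero.
    """
    pis, thetas, ds = [], [], []
    for r in range(n_replicates):
        _, aln, _ = simulate_coalescent_snps(n, L, theta_site, seed=seed + r)
        pis.append(nucleotide_diversity(aln)[1])
        thetas.append(watterson_theta(segregating_sites(aln), n, L)[1])
        d, defined = tajimas_d(aln)
        if defined:
            ds.append(d)
    pis, thetas = np.asarray(pis), np.asarray(thetas)
    return NeutralCalibration(
        theta_true=theta_site,
        mean_pi_site=float(pis.mean()),
        se_pi_site=float(pis.std(ddof=1) / np.sqrt(len(pis))),
        mean_theta_site=float(thetas.mean()),
        se_theta_site=float(thetas.std(ddof=1) / np.sqrt(len(thetas))),
        mean_tajima_d=float(np.mean(ds)),
        n_replicates=n_replicates,
    )


@dataclass
class OmegaRecovery:
    omega_true: float
    median_omega_hat: float
    power: float              # fraction of replicates called Non-neutral
    n_replicates: int


def omega_recovery(omega: float = 0.1, n_codons: int = 500, t: float = 0.3,
                   kappa: float = 2.0, n_replicates: int = 50,
                   seed: int = 0) -> OmegaRecovery:
    """Fit the codon model to pairs simulated at a known omega.

    Reports the median fitted omega and the fraction of replicates the LRT
    classifies as non-neutral (power when omega != 1, type-I error rate
    when omega == 1).
    """
    from .simulate import simulate_codon_pair

    omegas, rejections = [], 0
    for r in range(n_replicates):
        a, b, _ = simulate_codon_pair(n_codons, t, kappa, omega, seed=seed + r)
        res = evaluate_pair_neutrality(build_codon_alignment(a, b))
        omegas.append(res.omega_hat)
        rejections += res.classification == "Non-neutral"
    return OmegaRecovery(omega, float(np.median(omegas)),
                         rejections / n_replicates, n_replicates)


def assembly_round_trip_rate(n_accessions: int = 100, L: int = 800,
                             theta_site: float = 0.02, seed: int = 0,
                             qual_min: float = 25.0) -> dict[str, float]:
    """Simulate SNPs, assemble every accession, and check the round trip.

    Returns the fraction of accessions whose variant-vs-reference diff
    recovers exactly the quality-passing SNP set, and the fraction whose
    reference-allele reconstruction equals the reference.
    """
    table, aln, _ = simulate_coalescent_snps(n_accessions, L, theta_site, seed=seed)
    ref = list(aln.matrix[0])
    for r in table.for_accession(table.roster[0]).itertuples(index=False):
        ref[r.pos - 1] = r.ref
    reference = "".join(ref)
    assembled, reports = assemble_alignment(("chr1", 1, L), reference, table,
                                            qual_min=qual_min)
    diff_ok = recon_ok = 0
    for i, acc in enumerate(table.roster):
        expected = {(int(r.pos), r.ref, r.alt)
                    for r in table.for_accession(acc).itertuples(index=False)
                    if r.qual >= qual_min}
        variant = "".join(assembled.matrix[i])
        diff_ok += set(diff_sequences(reference, variant)) == expected
        recon_ok += reports[i].colzero_identity
    return {"diff_recovery_rate": diff_ok / n_accessions,
            "reconstruction_identity_rate": recon_ok / n_accessions}


def window_band_detection_rate(n_seeds: int = 20, n_accessions: int = 24,
                               theta_background: float = 0.004,
                               theta_band: float = 0.04,
                               n_boot: int = 100, alpha: float = 0.05,
                               min_band_fraction: float = 0.8,
                               seed: int = 0) -> float:
    """How often the window pipeline flags a planted high-diversity band.

    Three latitude groups are simulated over a 2.5 kb promoter; the focal
    group carries elevated diversity in the -1600..-500 band.  A seed
    counts as a detection when at least ``min_band_fraction`` of the
    in-band window comparisons are significant.
    """
    base = [(900, theta_background), (1100, theta_background),
            (500, theta_background)]
    hot = [(900, theta_background), (1100, theta_band), (500, theta_background)]
    detections = 0
    for s in range(n_seeds):
        alns = {}
        for i, group in enumerate(["40-45", "45-50", "50-60"]):
            segs = hot if group == "45-50" else base
            _, aln, _ = simulate_structured_region(
                n_accessions, segs, seed=seed + 1000 * s + i)
            alns[group] = aln
        table = compare_window_profiles(alns, "45-50", alpha=alpha,
                                        n_boot=n_boot, seed=seed + s)
        in_band = table[(table.window_start >= -1600) & (table.window_end <= -500)]
        frac = in_band[["sig_vs_40-45", "sig_vs_50-60"]].to_numpy().mean()
        detections += frac >= min_band_fraction
    return detections / n_seeds


def blob_recovery_exact(seed: int = 0, per_blob: int = 6, spread: float = 0.3,
                        separation: float = 10.0) -> bool:
    """Does a k=3 cut recover three well-separated planted blobs exactly?"""
    rng = np.random.default_rng(seed)
    centers = [(0.0, 0.0, 0.0), (separation, separation, 0.0),
               (-separation, 0.0, separation)]
    rows, truth = [], {}
    for b, center in enumerate(centers):
        for i in range(per_blob):
            name = f"g{b}_{i}"
            rows.append(rng.normal(center, spread))
            truth[name] = b
    matrix = pd.DataFrame(rows, index=list(truth))
    _, part = cluster_statistic_matrix(matrix, k=3)
    mapping: dict[int, int] = {}
    for gene, blob in truth.items():
        mapping.setdefault(blob, part[gene])
        if part[gene] != mapping[blob]:
            return False
    return len(set(mapping.values())) == 3
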