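"""Synthetic neutrophil-cohort generator with full ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be exercised and checked against known truth
without any external download:

* 68 healthy donors + 16 patients split over processing-date batches;
* heavy-tailed log2-normal protein abundances spanning >= 4 orders of
  magnitude, with the top ``top_k_half`` proteins (default 7) analytically
  rescaled to hold exactly half of the total linear abundance — the extreme
  concentration seen in granulocytes, whose proteome is dominated by a few
  antimicrobial proteins;
* per-protein biological variances drawn from a scaled inverse-chi-square
  (prior df ``d0_true``, scale ``s0sq_true``) — the model the moderated-t
  machinery estimates back;
* per-(batch, protein) location shifts and per-batch variance inflation —
  the model ComBat estimates back;
* disease signatures as fixed log2 offsets on named proteins (e.g. a
  16-fold CYBA-like or 84-fold CYBB-like knockdown);
* technical replicate noise tuned so same-subject replicates correlate at
  about 0.87 on the log2 scale;
* RNA counts whose log-means are, by default, independent of protein
  means (the striking protein/mRNA decoupling of mature neutrophils).

The cell model, on the log2 scale:

    x_ps = m_p + gamma[b(s), p] + signature_p(s) + eps,
    eps ~ Normal(0, delta[b(s)] * sigma_p^2)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (
    SCALE_LINEAR,
    SCALE_LOG2,
    ExpressionMatrix,
    PeptideSupport,
    ProteinAnnotation,
    SampleTable,
)

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "SyntheticCohort",
    "default_patient_roster",
    "generate_cohort",
    "generate_replicates",
    "generate_rna_counts",
]

# Disease-relevant marker proteins given real gene symbols so the synthetic
# signatures read like the diseases they imitate. Offsets are log2 units.
_SCN_SIGNATURE = {
    "ELANE": -np.log2(4.5),
    "AZU1": -np.log2(4.5),
    "CAMP": -np.log2(5.0),
    "HSPA5": 1.5,
    "PDIA4": 1.2,
    "RPL22": 1.0,
}
_CGD_SIGNATURE = {
    "CYBA": -np.log2(16.0),
    "CYBB": -np.log2(84.0),
    "LTF": -1.0,
    "MX1": 1.5,
    "STAT2": 1.2,
}
_LAD_SIGNATURE = {
    "ITGB2": -2.0,
    "ITGAM": -1.5,
    "ITGAX": -1.2,
    "CRISP3": -1.0,
}
_NCF1_SIGNATURE = {"NCF1": -5.0}
_RAB27A_SIGNATURE = {"RAB27A": -np.log2(100.0), "SYTL1": -1.5}

NAMED_SIGNATURES: dict[str, dict[str, float]] = {
    "scn-elane": _SCN_SIGNATURE,
    "cgd": _CGD_SIGNATURE,
    "lad": _LAD_SIGNATURE,
    "ncf1-deficiency": _NCF1_SIGNATURE,
    "rab27a-deficiency": _RAB27A_SIGNATURE,
}

_MARKER_GENES = sorted(
    {g for sig in NAMED_SIGNATURES.values() for g in sig}
)

_HISTONE_GENES = ("H2AC20", "H2BC11", "H3C1", "H4C1", "H1-2", "H2AZ1")


def default_patient_roster() -> list[tuple[str, str]]:
    """(group label, signature name) per patient: 6 SCN, 5 CGD, 3 LAD, 2 unresolved."""
    roster = [("SCN-ELANE", "scn-elane")] * 6
    roster += [("CGD", "cgd")] * 5
    roster += [("LAD", "lad")] * 3
    roster += [
        ("other-patient", "ncf1-deficiency"),
        ("other-patient", "rab27a-deficiency"),
    ]
    return roster


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults are the study-like conditions."""

    n_proteins: int = 4154
    n_healthy: int = 68
    patients: list[tuple[str, str]] = field(default_factory=default_patient_roster)
    n_batches: int = 6
    seed: int = 0
    mu0: float = 20.0  # log2 center of protein means
    sd0: float = 2.0  # log2 spread of protein means (~4 orders of magnitude)
    d0_true: float = 4.0  # prior df of per-protein variances
    s0sq_true: float = 0.04  # prior scale of per-protein variances
    batch_shift_sd: float = 0.3  # tau, log2 units
    batch_scale_shape: float = 40.0  # Gamma shape of per-batch variance inflation
    top_k_half: int = 7  # proteins holding 50% of linear abundance
    replicate_noise_sd: float = 0.78  # log2; gives same-subject PCC ~ 0.87
    peptide_a: float = -6.0  # peptide-count link: 1 + Poisson(a + b * m_p)
    peptide_b: float = 0.5
    missing_rate: float = 0.0  # optional MCAR switch
    # extra signatures (name -> {gene symbol: log2 offset}) usable in
    # `patients`, taking precedence over the built-in disease signatures
    custom_signatures: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_healthy < 2:
            raise ValueError("n_healthy must be >= 2")
        if self.d0_true <= 0 or self.s0sq_true < 0:
            # s0sq_true == 0 is the noise-free limit (every sample equals
            # its expectation), useful for degenerate-case tests
            raise ValueError("variance hyperparameters must be positive")
        if not (1 <= self.top_k_half <= self.n_proteins):
            raise ValueError("top_k_half must be in [1, n_proteins]")
        for sd in (self.sd0, self.batch_shift_sd, self.replicate_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class CohortTruth:
    """Everything needed to predict the expectation of every generated cell."""

    protein_means: pd.Series  # m_p, log2
    protein_variances: pd.Series  # sigma_p^2
    batch_locations: pd.DataFrame  # batch × protein, gamma
    batch_scales: pd.Series  # delta per batch
    signatures: dict[str, dict[str, float]]  # patient sample -> offsets
    subject_effects: pd.DataFrame  # protein × subject realized deviations
    sample_subjects: pd.Series  # sample -> subject
    sample_batches: pd.Series  # sample -> batch
    config: CohortConfig

    def expected_log2(self, sample_id: str) -> pd.Series:
        base = self.protein_means + self.batch_locations.loc[
            self.sample_batches[sample_id]
        ]
        for gene, off in self.signatures.get(sample_id, {}).items():
            base[gene] += off
        return base

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "protein_means": self.protein_means.to_dict(),
            "protein_variances": self.protein_variances.to_dict(),
            "batch_locations": {
                b: self.batch_locations.loc[b].to_dict()
                for b in self.batch_locations.index
            },
            "batch_scales": self.batch_scales.to_dict(),
            "signatures": self.signatures,
            "sample_subjects": self.sample_subjects.to_dict(),
            "sample_batches": self.sample_batches.to_dict(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


@dataclass
class SyntheticCohort:
    matrix: ExpressionMatrix  # linear scale
    samples: SampleTable
    peptides: PeptideSupport
    annotations: dict[str, ProteinAnnotation]
    truth: CohortTruth


def _protein_ids(n: int) -> list[str]:
    """Synthetic accessions; marker and histone genes take real symbols."""
    return [f"P{i:05d}" for i in range(n)]


def _gene_symbols(n: int) -> list[str]:
    genes = [f"GENE{i:05d}" for i in range(n)]
    # reserve deterministic slots (spread out, away from the rescaled top)
    special = list(_MARKER_GENES) + list(_HISTONE_GENES)
    if n < len(special) + 50:
        raise ValueError(f"need at least {len(special) + 50} proteins")
    step = max((n - 50) // len(special), 1)
    for k, gene in enumerate(special):
        genes[50 + k * step] = gene
    return genes


def _rescale_top_half(
    linear_means: np.ndarray, k: int, margin: float = 1e-6
) -> np.ndarray:
    """Scale the k largest linear means so they hold just over half the total.

    The top-k block is scaled to sum to (1 + margin) x the rest, putting
    its share a hair above 0.5 (robust to float rounding) while the
    (k-1)-share stays below 0.5 — so the smallest count reaching 50% is
    exactly k.  If proportional scaling would break the abundance order,
    the block is redistributed above a floor just over the largest
    non-top protein.  Infeasible when the rest sums to zero.
    """
    order = np.argsort(-linear_means)
    top, rest = order[:k], order[k:]
    s_top = float(linear_means[top].sum())
    s_rest = float(linear_means[rest].sum())
    if s_rest <= 0 or s_top <= 0:
        raise ValueError(f"top_k_half={k} rescaling infeasible for this profile")
    target = s_rest * (1.0 + margin)
    out = linear_means.copy()
    out[top] = linear_means[top] * (target / s_top)
    if out[top].min() <= linear_means[rest].max():
        floor = 1.005 * float(linear_means[rest].max())
        remainder = target - k * floor
        if remainder <= 0:
            raise ValueError(
                f"top_k_half={k} rescaling cannot preserve the abundance order"
            )
        out[top] = floor + remainder * (linear_means[top] / s_top)
    return out


def generate_cohort(config: Optional[CohortConfig] = None) -> SyntheticCohort:
    """Draw a full synthetic cohort plus its ground truth.

    Deterministic under a fixed ``config.seed``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n_prot = config.n_proteins

    protein_ids = _protein_ids(n_prot)
    genes = _gene_symbols(n_prot)
    gene_to_pid = {g: p for p, g in zip(protein_ids, genes)}

    # per-protein log2 means, heavy concentration forced analytically
    m = rng.normal(config.mu0, config.sd0, size=n_prot)
    linear = _rescale_top_half(2.0 ** m, config.top_k_half)
    m = np.log2(linear)
    m_series = pd.Series(m, index=protein_ids, name="m")

    # scaled inverse-chi-square variances
    sigma_sq = (
        config.d0_true
        * config.s0sq_true
        / rng.chisquare(config.d0_true, size=n_prot)
    )
    sigma_sq_series = pd.Series(sigma_sq, index=protein_ids, name="sigma_sq")

    # samples: healthy donors then patients, batches assigned round-robin
    # after a seeded shuffle so batch is not confounded with group
    healthy_ids = [f"HD{i:03d}" for i in range(1, config.n_healthy + 1)]
    patient_ids = [f"PT{i:02d}" for i in range(1, len(config.patients) + 1)]
    sample_ids = healthy_ids + patient_ids
    batch_labels = [f"batch{j + 1}" for j in range(config.n_batches)]
    shuffled = list(sample_ids)
    rng.shuffle(shuffled)
    batch_of = {s: batch_labels[i % config.n_batches] for i, s in enumerate(shuffled)}

    groups = ["healthy"] * config.n_healthy + [g for g, _ in config.patients]
    signature_names = [None] * config.n_healthy + [s for _, s in config.patients]

    gamma = rng.normal(
        0.0, config.batch_shift_sd, size=(config.n_batches, n_prot)
    )
    gamma_df = pd.DataFrame(gamma, index=batch_labels, columns=protein_ids)
    shape = config.batch_scale_shape
    delta = (
        rng.gamma(shape, 1.0 / shape, size=config.n_batches)
        if shape > 0
        else np.ones(config.n_batches)
    )
    delta_series = pd.Series(delta, index=batch_labels, name="delta")

    signatures: dict[str, dict[str, float]] = {}
    subject_effects = rng.normal(
        0.0, np.sqrt(sigma_sq)[:, None], size=(n_prot, len(sample_ids))
    )
    values = np.empty((n_prot, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        b = batch_of[sid]
        bi = batch_labels.index(b)
        x = m + gamma[bi] + np.sqrt(delta[bi]) * subject_effects[:, j]
        sig_name = signature_names[j]
        if sig_name is not None:
            sig = (
                config.custom_signatures[sig_name]
                if sig_name in config.custom_signatures
                else NAMED_SIGNATURES[sig_name]
            )
            offsets = {}
            for gene, off in sig.items():
                pid = gene_to_pid[gene]
                x[protein_ids.index(pid)] += off
                offsets[pid] = float(off)
            signatures[sid] = offsets
        values[:, j] = x

    linear_values = 2.0 ** values
    if config.missing_rate > 0:
        mask = rng.random(linear_values.shape) < config.missing_rate
        linear_values[mask] = np.nan

    matrix = ExpressionMatrix(
        pd.DataFrame(linear_values, index=protein_ids, columns=sample_ids),
        scale=SCALE_LINEAR,
    )

    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "batch": [batch_of[s] for s in sample_ids],
                "subject_id": [f"SUBJ_{s}" for s in sample_ids],
                "timepoint": 1,
            }
        )
    )

    lam = np.maximum(config.peptide_a + config.peptide_b * m, 0.0)
    counts = 1 + rng.poisson(lam)
    peptides = PeptideSupport(dict(zip(protein_ids, counts)))

    mw = np.exp(rng.normal(np.log(4.0e4), 0.4, size=n_prot))
    histone_set = set(_HISTONE_GENES)
    annotations = {
        pid: ProteinAnnotation(
            protein_id=pid,
            gene_symbol=g,
            molecular_weight=float(w) if g not in histone_set else float(
                rng.uniform(1.1e4, 2.2e4)
            ),
            is_histone=g in histone_set,
        )
        for pid, g, w in zip(protein_ids, genes, mw)
    }

    truth = CohortTruth(
        protein_means=m_series,
        protein_variances=sigma_sq_series,
        batch_locations=gamma_df,
        batch_scales=delta_series,
        signatures=signatures,
        subject_effects=pd.DataFrame(
            subject_effects,
            index=protein_ids,
            columns=[f"SUBJ_{s}" for s in sample_ids],
        ),
        sample_subjects=pd.Series(
            {s: f"SUBJ_{s}" for s in sample_ids}, name="subject"
        ),
        sample_batches=pd.Series(batch_of, name="batch").reindex(sample_ids),
        config=config,
    )
    return SyntheticCohort(matrix, samples, peptides, annotations, truth)


def generate_replicates(
    truth: CohortTruth, subject: str, k: int, seed: int
) -> ExpressionMatrix:
    """Re-draw ``k`` replicate profiles of one subject.

    Replicates share the subject's realized per-protein profile
    (m_p + the subject's biological deviation) and differ only by
    technical noise of sd ``replicate_noise_sd``; no batch effects are
    applied.  Pairwise log2 Pearson correlation is then
    Var(profile) / (Var(profile) + noise^2) across proteins.
    """
    if k < 2:
        raise ValueError("need at least 2 replicates")
    if subject not in truth.subject_effects.columns:
        raise ValueError(f"unknown subject {subject!r}")
    # distinct stream so replicate noise never aliases the cohort draws
    rng = np.random.default_rng([seed, 0x5245])
    profile = (
        truth.protein_means.to_numpy()
        + truth.subject_effects[subject].to_numpy()
    )
    sample_id = truth.sample_subjects[truth.sample_subjects == subject].index[0]
    for pid, off in truth.signatures.get(sample_id, {}).items():
        profile[truth.protein_means.index.get_loc(pid)] += off
    noise = rng.normal(
        0.0, truth.config.replicate_noise_sd, size=(profile.size, k)
    )
    values = profile[:, None] + noise
    cols = [f"{subject}_rep{i + 1}" for i in range(k)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=truth.protein_means.index, columns=cols),
        scale=SCALE_LOG2,
    )


def generate_rna_counts(
    config: CohortConfig,
    truth: CohortTruth,
    annotations: dict[str, ProteinAnnotation],
    n_samples: int = 22,
    seed: int = 0,
    rho: float = 0.0,
    dispersion: float = 10.0,
    mean_log_tpm_like: float = 4.0,
    sd_log: float = 1.5,
    lib_size: float = 2.0e7,
) -> pd.DataFrame:
    """Negative-binomial RNA counts with tunable protein coupling.

    ``rho`` is the correlation between gene-level log RNA means and the
    (standardized) protein log2 means; the default 0 reproduces the
    protein/mRNA decoupling of mature neutrophils.  ``dispersion`` is the
    NB size parameter (var = mu + mu^2 / size; size -> inf approaches
    Poisson).  Returns a tidy table with gene_symbol, exon_union_length,
    and one count column per sample.
    """
    if dispersion <= 0:
        raise ValueError("dispersion (NB size) must be positive")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    # distinct stream so RNA means are independent of the protein draws
    rng = np.random.default_rng([seed, 0x524E])
    pids = truth.protein_means.index
    genes = [annotations[p].gene_symbol for p in pids]
    m = truth.protein_means.to_numpy()
    m_std = (m - m.mean()) / m.std()
    indep = rng.normal(0.0, 1.0, size=m.size)
    log_mean = mean_log_tpm_like + sd_log * (
        rho * m_std + np.sqrt(max(0.0, 1.0 - rho * rho)) * indep
    )
    rel = np.exp(log_mean)
    rel = rel / rel.sum()
    mu = rel * lib_size
    lengths = np.exp(rng.normal(np.log(3000.0), 0.6, size=m.size)).round().astype(int)
    lengths = np.maximum(lengths, 200)
    p = dispersion / (dispersion + mu)
    counts = {
        f"RNA{s + 1:02d}": rng.negative_binomial(dispersion, p)
        for s in range(n_samples)
    }
    return pd.DataFrame(
        {"gene_symbol": genes, "exon_union_length": lengths, **counts}
    )
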