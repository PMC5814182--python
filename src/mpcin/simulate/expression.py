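"""Paired tumor/adjacent expression counts with planted signature effects.

Counts are negative binomial around gene baseline means; tumor samples of a
pair have their signature-gene means multiplied by ``2**effect``. Per-sample
library-size factors are drawn and recorded in the manifest so that
count-scale normalization has something real to undo. The default planted
pattern mirrors elevated chromosomal-instability signature expression in
tumors with Foxm1 carrying the largest effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionSim:
    counts: pd.DataFrame        # genes x samples
    manifest: pd.DataFrame      # sample_id, subject_id, condition, lib_factor
    effects: dict[str, float]   # per-gene true log2 fold change (truth)


def simulate_expression(
    n_genes: int,
    n_pairs: int,
    signature_genes: list[str],
    effect_log2fc: dict[str, float] | float = 1.0,
    dispersion: float = 0.1,
    baseline_log_mean: float = 5.0,
    baseline_log_sd: float = 1.0,
    lib_factor_sd: float = 0.15,
    seed: int = 0,
) -> ExpressionSim:
    """Simulate a paired tumor/adjacent count matrix.

    ``effect_log2fc`` is either a per-gene mapping (genes missing from it
    get 0) or a scalar applied to every signature gene. Genes beyond the
    signature are filler genes named ``gene00001``... with zero effect.
    Deterministic for a fixed seed.
    """
    if dispersion <= 0:
        raise ValueError(f"dispersion must be positive, got {dispersion}")
    if n_pairs < 2:
        raise ValueError(f"n_pairs must be >= 2, got {n_pairs}")
    if len(signature_genes) > n_genes:
        raise ValueError("n_genes smaller than the signature")
    if len(set(signature_genes)) != len(signature_genes):
        raise ValueError("duplicate signature gene names")

    rng = np.random.default_rng(seed)
    fillers = [f"gene{i + 1:05d}" for i in range(n_genes - len(signature_genes))]
    genes = list(signature_genes) + fillers

    if isinstance(effect_log2fc, dict):
        effects = {g: float(effect_log2fc.get(g, 0.0)) for g in genes}
    else:
        effects = {g: (float(effect_log2fc) if g in signature_genes else 0.0) for g in genes}

    base = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=len(genes)))
    eff = np.array([effects[g] for g in genes])

    samples: list[str] = []
    subjects: list[str] = []
    conditions: list[str] = []
    factors: list[float] = []
    columns: dict[str, np.ndarray] = {}
    n_nb = 1.0 / dispersion
    for pair in range(n_pairs):
        subject = f"mouse{pair + 1}"
        for condition in ("tumor", "adjacent"):
            lib = float(np.exp(rng.normal(0.0, lib_factor_sd)))
            mu = base * (2.0**eff if condition == "tumor" else 1.0) * lib
            p = n_nb / (n_nb + mu)
            counts = rng.negative_binomial(n_nb, p)
            sid = f"{subject}_{condition}"
            samples.append(sid)
            subjects.append(subject)
            conditions.append(condition)
            factors.append(lib)
            columns[sid] = counts

    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    manifest = pd.DataFrame(
        {
            "sample_id": samples,
            "subject_id": subjects,
            "condition": conditions,
            "lib_factor": factors,
        }
    )
    return ExpressionSim(counts=counts, manifest=manifest, effects=effects)
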