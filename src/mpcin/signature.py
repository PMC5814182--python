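"""Chromosomal-instability signature scoring on paired expression data.

The paired tumor/adjacent comparison uses log2 CPM (counts per million,
pseudocount 1) per-subject differences: the per-gene statistic is the mean
difference across subjects, its significance an exact two-sided sign-flip
permutation p-value (all 2^n flips enumerated when feasible, otherwise a
random add-one-corrected subset), with Benjamini-Hochberg adjustment across
the signature genes. Genes are ranked by significance, then |log2FC|.

The shipped default signature is the 25-gene CIN25 list (FOXM1 among them);
matching is case-insensitive so mouse symbols map onto it. An unpaired
Mann-Whitney comparison is provided for cohort-style (e.g. TCGA tumor vs
adjacent) analyses.
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class SignatureResult:
    table: pd.DataFrame              # gene, log2fc, p_value, q_value, rank
    missing: list[str] = field(default_factory=list)

    def rank_of(self, gene: str) -> int:
        hit = self.table.index[self.table["gene"].str.lower() == gene.lower()]
        if len(hit) == 0:
            raise KeyError(gene)
        return int(self.table.loc[hit[0], "rank"])


def load_cin25() -> list[str]:
    """The packaged CIN25 signature gene list."""
    text = importlib.resources.files("mpcin.data").joinpath("cin25.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]


def cpm_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts-per-million and log2(cpm+1) per sample.

    Scale-invariant per sample; a zero-total sample is a hard error.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero.index))}")
    cpm = counts / totals * 1e6
    return cpm, np.log2(cpm + 1.0)


def _check_paired(manifest: pd.DataFrame) -> list[tuple[str, str, str]]:
    """Return (subject, tumor_sample, adjacent_sample) triples or raise."""
    required = {"sample_id", "subject_id", "condition"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    bad_cond = set(manifest["condition"]) - {"tumor", "adjacent"}
    if bad_cond:
        raise ValueError(f"unknown condition value(s): {sorted(bad_cond)}")
    if manifest["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in manifest")
    pairs = []
    broken = []
    for subject, group in manifest.groupby("subject_id", sort=True):
        tumors = group.loc[group["condition"] == "tumor", "sample_id"].tolist()
        adjacents = group.loc[group["condition"] == "adjacent", "sample_id"].tolist()
        if len(tumors) == 1 and len(adjacents) == 1:
            pairs.append((str(subject), tumors[0], adjacents[0]))
        else:
            broken.append(str(subject))
    if broken:
        raise ValueError(f"unpaired subject(s): {', '.join(broken)}")
    return pairs


def _sign_flip_pvalues(diffs: np.ndarray, B: int, seed: int) -> np.ndarray:
    """Two-sided sign-flip permutation p-values for each row of ``diffs``.

    Enumerates all 2^n flips when 2^n <= B (exact; the identity flip makes
    an all-zero gene return p = 1); otherwise uses B random flips with the
    add-one correction.
    """
    n = diffs.shape[1]
    observed = np.abs(diffs.mean(axis=1))
    if 2**n <= B:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        perm = np.abs(diffs @ signs.T) / n          # genes x 2^n
        hits = (perm >= observed[:, None] - 1e-12).sum(axis=1)
        return hits / signs.shape[0]
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(B, n))
    perm = np.abs(diffs @ signs.T) / n
    hits = (perm >= observed[:, None] - 1e-12).sum(axis=1)
    return (hits + 1) / (B + 1)


def paired_signature_test(
    counts: pd.DataFrame,
    manifest: pd.DataFrame,
    signature: list[str],
    B: int = 2000,
    seed: int = 0,
) -> SignatureResult:
    """Score a gene signature on a paired tumor/adjacent design.

    Signature genes absent from the matrix are reported in ``missing``,
    never silently dropped. Deterministic for a fixed seed; invariant to
    gene order and subject relabeling.
    """
    if B < 1000:
        raise ValueError(f"B must be >= 1000, got {B}")
    pairs = _check_paired(manifest)
    _, logcpm = cpm_normalize(counts)
    lower = {str(g).lower(): str(g) for g in counts.index}
    resolved: list[tuple[str, str]] = []   # (signature name, matrix name)
    missing: list[str] = []
    for gene in signature:
        key = gene.lower()
        if key in lower:
            resolved.append((gene, lower[key]))
        else:
            missing.append(gene)
    if not resolved:
        raise ValueError("no signature gene found in the expression matrix")

    rows = [logcpm.loc[name] for _, name in resolved]
    sig_mat = pd.DataFrame(rows, index=[sig for sig, _ in resolved])
    tumor = sig_mat[[t for _, t, _ in pairs]].to_numpy()
    adjacent = sig_mat[[a for _, _, a in pairs]].to_numpy()
    diffs = tumor - adjacent

    log2fc = diffs.mean(axis=1)
    pvals = _sign_flip_pvalues(diffs, B, seed)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene": [sig for sig, _ in resolved],
            "log2fc": log2fc,
            "p_value": pvals,
            "q_value": qvals,
        }
    )
    order = np.lexsort((-np.abs(table["log2fc"].to_numpy()), table["p_value"].to_numpy()))
    table = table.iloc[order].reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return SignatureResult(table=table, missing=missing)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U statistic of ``x``, p-value).

    Exact enumeration when |x|+|y| <= 12 with no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    combined = np.concatenate([x, y])
    tie_free = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)
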