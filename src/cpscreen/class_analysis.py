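"""Target-class enrichment and consolidation-entropy analysis.

Two questions about annotated compound classes:

* **Enrichment** — is a class phenotypically distinguishable?  Per class,
  the in-class pairwise fingerprint similarities are compared against the
  member-to-non-member similarities with a one-sided two-sample
  Kolmogorov–Smirnov test (alternative: in-class similarities are
  stochastically greater).  A small p means the class members look more
  like each other than like the rest of the screen.
* **Consolidation** — does cell activation make a class's phenotypes more
  uniform?  With active compounds clustered per condition (HDBSCAN on
  pairwise Euclidean fingerprint distances), each class gets a Shannon
  entropy (base 2) of its members' distribution over cluster labels; noise
  points (label −1) each count as their own singleton cluster.  A negative
  delta (activated − resting) means the class consolidated under
  activation.

The entropy functional is this module's documented reconstruction: cluster
labels and distances are injected, so alternative functionals can be
swapped without touching callers.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CPScreenError, get_logger

log = get_logger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class ClassEnrichmentResult:
    label: str
    n_members: int
    ks_statistic: float
    p_value: float
    p_adjusted: float
    significant: bool

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value)


@dataclass
class ClassEntropyResult:
    label: str
    n_members: int
    entropy_resting: float
    entropy_activated: float

    @property
    def delta(self) -> float:
        """activated − resting; negative means consolidation under activation."""
        return self.entropy_activated - self.entropy_resting


def _pair_values(sim: np.ndarray, members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    inside = sim[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    in_class = inside[iu]
    mask = np.ones(sim.shape[0], dtype=bool)
    mask[members] = False
    out_class = sim[np.ix_(members, np.where(mask)[0])].ravel()
    return in_class, out_class


def ks_class_enrichment(
    similarity: pd.DataFrame,
    classes: dict[str, frozenset[str]],
    alpha: float = DEFAULT_ALPHA,
) -> list[ClassEnrichmentResult]:
    """One-sided KS enrichment of in-class vs out-of-class similarities.

    ``similarity`` is a square compound-by-compound matrix; ``classes`` maps
    compound → class labels.  Classes with fewer than 2 members present in
    the matrix are skipped with a warning.  Raw p-values make the default
    significance call; Benjamini–Hochberg-adjusted values are reported
    alongside.
    """
    keys = list(similarity.index)
    pos = {k: i for i, k in enumerate(keys)}
    by_class: dict[str, list[int]] = {}
    for cid, labels in classes.items():
        if cid not in pos:
            continue
        for lab in labels:
            by_class.setdefault(lab, []).append(pos[cid])
    sim = similarity.to_numpy(dtype=float)
    results = []
    for lab in sorted(by_class):
        members = np.array(sorted(by_class[lab]))
        if len(members) < 2:
            log.warning("class %s has <2 annotated members in the matrix; skipped", lab)
            continue
        in_class, out_class = _pair_values(sim, members)
        if out_class.size == 0:
            log.warning("class %s covers every compound; skipped", lab)
            continue
        # alternative='less': the in-class CDF lies below, i.e. in-class
        # similarities are stochastically greater
        ks = stats.ks_2samp(in_class, out_class, alternative="less")
        results.append(
            ClassEnrichmentResult(
                label=lab,
                n_members=len(members),
                ks_statistic=float(ks.statistic),
                p_value=float(max(ks.pvalue, np.finfo(float).tiny)),
                p_adjusted=np.nan,
                significant=bool(ks.pvalue < alpha),
            )
        )
    if results:
        adj = stats.false_discovery_control([r.p_value for r in results], method="bh")
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
    return results


def enrichment_frame(results: list[ClassEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [r.label for r in results],
            "n_members": [r.n_members for r in results],
            "ks_statistic": [r.ks_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "neg_log10_p": [r.neg_log10_p for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
        }
    )


def membership_entropy(cluster_labels) -> float:
    """Shannon entropy (base 2) of a class's distribution over clusters.

    Noise labels (−1) are each treated as their own singleton cluster, so a
    fully noise-scattered class has maximal entropy while a class fused into
    one cluster has entropy 0.
    """
    labels = list(cluster_labels)
    if not labels:
        raise CPScreenError("no members to compute entropy over")
    counts = Counter()
    noise = 0
    for lab in labels:
        if lab == -1:
            counts[f"noise_{noise}"] = 1
            noise += 1
        else:
            counts[lab] += 1
    n = len(labels)
    return float(-sum((c / n) * math.log2(c / n) for c in counts.values()))


def entropy_consolidation(
    labels_resting: pd.Series,
    labels_activated: pd.Series,
    classes: dict[str, frozenset[str]],
) -> list[ClassEntropyResult]:
    """Per-class membership entropy in each condition.

    ``labels_*`` map active compounds to their cluster label in that
    condition (from HDBSCAN on pairwise Euclidean fingerprint distances).
    Classes need ≥2 active members in both conditions; others are skipped
    with a warning.
    """
    by_class: dict[str, list[str]] = {}
    for cid, labs in classes.items():
        for lab in labs:
            by_class.setdefault(lab, []).append(cid)
    results = []
    for lab in sorted(by_class):
        members_r = [c for c in by_class[lab] if c in labels_resting.index]
        members_a = [c for c in by_class[lab] if c in labels_activated.index]
        if len(members_r) < 2 or len(members_a) < 2:
            log.warning("class %s lacks >=2 active members in both conditions; skipped", lab)
            continue
        results.append(
            ClassEntropyResult(
                label=lab,
                n_members=len(set(members_r) | set(members_a)),
                entropy_resting=membership_entropy(labels_resting[members_r]),
                entropy_activated=membership_entropy(labels_activated[members_a]),
            )
        )
    return results


def consolidation_scatter(results: list[ClassEntropyResult]) -> pd.DataFrame:
    """Plot-ready table: x = resting entropy, y = activated entropy,
    marker size = members, and a direction flag (consolidated iff the
    activated entropy is lower)."""
    return pd.DataFrame(
        {
            "class": [r.label for r in results],
            "entropy_resting": [r.entropy_resting for r in results],
            "entropy_activated": [r.entropy_activated for r in results],
            "n_members": [r.n_members for r in results],
            "delta": [r.delta for r in results],
            "direction": [
                "consolidated" if r.delta < 0 else ("dispersed" if r.delta > 0 else "unchanged")
                for r in results
            ],
        },
        columns=["class", "entropy_resting", "entropy_activated", "n_members", "delta", "direction"],
    )
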