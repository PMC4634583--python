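"""miRNA-pair functional similarity from target-gene-set comparison.

The gene-pair score matrix between two miRNAs' target sets is collapsed
with a modified best-match average: the sum of row maxima plus the sum of
column maxima, divided by the total number of *in-network* target genes,
(m - m') + (n - n').  Target genes absent from the weighted network are
excluded from both numerator and denominator (their counts m', n' are
recorded).  A Jaccard overlap of the raw target sets is provided as the
baseline the network method is meant to improve on — in sparse plant
target sets it is almost always zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import WeightedNetwork
from .pathsim import PathSearchConfig, all_pairs_gene_scores

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetGeneSet:
    """A miRNA's (deduplicated) predicted target genes."""

    mirna: str
    targets: frozenset

    @classmethod
    def from_iterable(cls, mirna: str, targets: Iterable[str]) -> "TargetGeneSet":
        return cls(mirna, frozenset(targets))

    def effective(self, net: WeightedNetwork) -> Tuple[str, ...]:
        """The in-network subset, in sorted order."""
        return tuple(sorted(g for g in self.targets if g in net))

    def excluded_count(self, net: WeightedNetwork) -> int:
        return len(self.targets) - len(self.effective(net))


@dataclass
class TargetSetSimilarity:
    """Modified-BMA similarity of two miRNAs' target sets.

    ``status`` is ``"undefined"`` (score ``None``) when both effective
    sets are empty — the denominator would be zero; when exactly one is
    empty the score degenerates to 0.
    """

    mirna_i: str
    mirna_j: str
    score: Optional[float]
    m: int
    n: int
    m_excluded: int
    n_excluded: int
    status: str = "ok"


def target_set_similarity(
    set_i: TargetGeneSet,
    set_j: TargetGeneSet,
    net: WeightedNetwork,
    cfg: PathSearchConfig = PathSearchConfig(),
) -> TargetSetSimilarity:
    """Score one miRNA pair by the modified BMA over its gene-pair matrix."""
    eff_i = set_i.effective(net)
    eff_j = set_j.effective(net)
    m, n = len(set_i.targets), len(set_j.targets)
    mx, nx_ = m - len(eff_i), n - len(eff_j)
    if not eff_i and not eff_j:
        return TargetSetSimilarity(
            set_i.mirna, set_j.mirna, None, m, n, mx, nx_, status="undefined"
        )
    if not eff_i or not eff_j:
        logger.warning(
            "one-sided empty effective target set for (%s, %s); score degenerates to 0",
            set_i.mirna,
            set_j.mirna,
        )
        return TargetSetSimilarity(set_i.mirna, set_j.mirna, 0.0, m, n, mx, nx_)
    matrix = all_pairs_gene_scores(eff_i, eff_j, net, cfg).to_numpy()
    score = bma_from_matrix(matrix)
    return TargetSetSimilarity(set_i.mirna, set_j.mirna, score, m, n, mx, nx_)


def bma_from_matrix(matrix: np.ndarray) -> float:
    """(sum of row maxima + sum of column maxima) / (rows + cols)."""
    rows, cols = matrix.shape
    return float(
        (matrix.max(axis=1).sum() + matrix.max(axis=0).sum()) / (rows + cols)
    )


@dataclass
class SimilarityMatrix:
    """Symmetric miRNA-by-miRNA similarity table with unit diagonal.

    Undefined entries (both target sets entirely outside the network) are
    stored as NaN and serialized as ``NA``, never 0.
    """

    mirnas: List[str]
    values: np.ndarray
    aspect: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mirnas, columns=self.mirnas)

    def to_tsv(self, path: str, precision: int = 6) -> None:
        frame = self.to_frame().round(precision)
        frame.to_csv(path, sep="\t", na_rep="NA", float_format=f"%.{precision}f")

    def entry(self, a: str, b: str) -> float:
        i, j = self.mirnas.index(a), self.mirnas.index(b)
        return float(self.values[i, j])


def all_pairs_matrix(
    sets: Sequence[TargetGeneSet],
    net: WeightedNetwork,
    cfg: PathSearchConfig = PathSearchConfig(),
) -> SimilarityMatrix:
    """All-pairs miRNA similarity; gene-pair scores are cached across pairs."""
    if len(sets) < 2:
        raise ValueError("need at least two miRNAs for an all-pairs matrix")
    k = len(sets)
    values = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            result = target_set_similarity(sets[i], sets[j], net, cfg)
            values[i, j] = values[j, i] = (
                np.nan if result.score is None else result.score
            )
    return SimilarityMatrix([s.mirna for s in sets], values, net.aspect)


def jaccard_similarity(set_i: TargetGeneSet, set_j: TargetGeneSet) -> float:
    """|intersection| / |union| of the raw target sets (network-agnostic)."""
    union = set_i.targets | set_j.targets
    if not union:
        raise ValueError("Jaccard similarity undefined: both target sets empty")
    return len(set_i.targets & set_j.targets) / len(union)


def load_target_table(path: str) -> Dict[str, TargetGeneSet]:
    """Read a 2-column (mirna, target gene) TSV into per-miRNA target sets."""
    raw: Dict[str, set] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"target table line has <2 columns: {line!r}")
            raw.setdefault(cols[0], set()).add(cols[1])
    return {m: TargetGeneSet(m, frozenset(t)) for m, t in raw.items()}
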