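"""Agreement between molecular delimitation and morphospecies partitions.

Each molecular group is classified against the morphospecies partition:
``match`` (coincides exactly with one morphospecies), ``split`` (strictly
inside one morphospecies: morphology lumps what DNA separates), ``lump``
(union of two or more complete morphospecies: DNA joins what morphology
separates) or ``mixed`` (straddles morphospecies without clean containment).
Overall agreement is summarised by the adjusted Rand index, a pair-counting
index corrected for chance agreement (1 for identical partitions, ~0 for
independent ones).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .errors import DataError

logger = logging.getLogger(__name__)

CLASSES = ("match", "split", "lump", "mixed")


@dataclass
class PartitionComparison:
    per_group: dict[str, str]        # molecular group id -> class
    class_counts: dict[str, int]
    adjusted_rand: float
    n_tips: int

    def __post_init__(self):
        if sum(self.class_counts.values()) != len(self.per_group):
            raise DataError("class counts do not sum to group count")


def compare_partitions(mol: dict[str, str], morph: dict[str, str]
                       ) -> PartitionComparison:
    """Classify molecular groups against morphospecies labels and compute
    the chance-adjusted pair-counting agreement.

    Tips lacking a label in either partition are excluded with a warning;
    completely disjoint tip universes are an error.
    """
    common = sorted(set(mol) & set(morph))
    if not common:
        raise DataError("molecular and morphospecies partitions share no tips")
    skipped = (set(mol) | set(morph)) - set(common)
    if skipped:
        logger.warning("excluding %d tips unlabelled in one partition",
                       len(skipped))
    mol_sets: dict[str, set[str]] = {}
    morph_sets: dict[str, set[str]] = {}
    for tip in common:
        mol_sets.setdefault(mol[tip], set()).add(tip)
        morph_sets.setdefault(morph[tip], set()).add(tip)

    per_group: dict[str, str] = {}
    for gid, tips in mol_sets.items():
        touched = [mset for mset in morph_sets.values() if mset & tips]
        if len(touched) == 1:
            per_group[gid] = "match" if touched[0] == tips else "split"
        elif all(mset <= tips for mset in touched):
            per_group[gid] = "lump"
        else:
            per_group[gid] = "mixed"
    counts = {c: sum(1 for v in per_group.values() if v == c)
              for c in CLASSES}
    ari = float(adjusted_rand_score([mol[t] for t in common],
                                    [morph[t] for t in common]))
    return PartitionComparison(per_group=per_group, class_counts=counts,
                               adjusted_rand=ari, n_tips=len(common))


def comparison_table(cmp: PartitionComparison) -> pd.DataFrame:
    return pd.DataFrame(
        [{"group": g, "class": c} for g, c in sorted(cmp.per_group.items())]
    )
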