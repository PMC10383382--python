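"""Similarity-weighted read-across prediction of toxicity outcomes.

Generalized read-across (GenRA-style): a target chemical's binary
activity is predicted as the similarity-weighted mean of the activities
of its most similar structural analogues,
``score = sum(s_i * a_i) / sum(s_i)`` over the ``k`` nearest analogues.

Fingerprints default to RDKit MACCS substructure keys as a generic,
openly available substitute for proprietary chemotype schemes; any
binary fingerprint array can be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .metrics import roc_auc


def maccs_fingerprint(smiles: str) -> np.ndarray:
    """MACCS substructure keys (167 bits) as a 0/1 integer array."""
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    fp = MACCSkeys.GenMACCSKeys(mol)
    return np.array(fp, dtype=int)


def jaccard_similarity(fp_a: Sequence[int], fp_b: Sequence[int]) -> float:
    """Jaccard/Tanimoto similarity |A∩B| / |A∪B| of binary vectors."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("both fingerprints are all-zero; similarity undefined")
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class Analogue:
    fingerprint: np.ndarray
    activity: float  # binary flag (0/1) or binarized dose outcome
    similarity: Optional[float] = None
    label: str = ""


@dataclass
class AnalogueSet:
    """A target fingerprint with its candidate source analogues.

    Similarities to the target are computed lazily (Jaccard) when not
    supplied.  Dose-valued activities can be binarized with
    :meth:`binarize`.
    """

    target_fingerprint: Optional[np.ndarray]
    analogues: list[Analogue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.analogues:
            raise ValueError("need at least one analogue")
        for a in self.analogues:
            if a.similarity is not None and not 0.0 <= a.similarity <= 1.0:
                raise ValueError(f"similarity out of [0,1]: {a.similarity}")

    @classmethod
    def from_smiles(
        cls,
        target_smiles: str,
        analogue_records: Sequence[tuple[str, float]] | Sequence[tuple[str, float, str]],
    ) -> "AnalogueSet":
        """Build from SMILES: records are (smiles, activity[, label])."""
        target = maccs_fingerprint(target_smiles)
        analogues = []
        for rec in analogue_records:
            smiles, activity = rec[0], rec[1]
            label = rec[2] if len(rec) > 2 else smiles
            fp = maccs_fingerprint(smiles)
            analogues.append(
                Analogue(fp, float(activity), jaccard_similarity(target, fp), label)
            )
        return cls(target, analogues)

    def with_similarities(self) -> "AnalogueSet":
        """Fill in missing similarities against the target fingerprint."""
        if all(a.similarity is not None for a in self.analogues):
            return self
        if self.target_fingerprint is None:
            raise ValueError("cannot compute similarities without a target fingerprint")
        filled = [
            Analogue(
                a.fingerprint,
                a.activity,
                a.similarity if a.similarity is not None
                else jaccard_similarity(self.target_fingerprint, a.fingerprint),
                a.label,
            )
            for a in self.analogues
        ]
        return AnalogueSet(self.target_fingerprint, filled)

    def binarize(self, dose_cutoff: float) -> "AnalogueSet":
        """Binarize dose-valued activities: active (1) at or below cutoff."""
        recs = [
            Analogue(a.fingerprint, 1.0 if a.activity <= dose_cutoff else 0.0,
                     a.similarity, a.label)
            for a in self.analogues
        ]
        return AnalogueSet(self.target_fingerprint, recs)


def genra_predict(aset: AnalogueSet, k: int = 10) -> dict:
    """Similarity-weighted activity score over the k most similar analogues.

    ``score = sum(s_i * a_i) / sum(s_i)``, a convex combination of the
    neighbour activities, so it always lies between the minimum and
    maximum analogue activity.  Similarity ties are broken by input
    order (stable sort); the analogues actually used are reported.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    aset = aset.with_similarities()
    order = sorted(
        range(len(aset.analogues)),
        key=lambda i: -aset.analogues[i].similarity,
    )  # stable: ties keep input order
    chosen = order[:k]
    sims = np.array([aset.analogues[i].similarity for i in chosen])
    acts = np.array([aset.analogues[i].activity for i in chosen])
    total = sims.sum()
    if total == 0:
        raise ValueError("all similarities are zero; score undefined")
    return {
        "score": float((sims * acts).sum() / total),
        "used": chosen,
        "k": len(chosen),
    }


def genra_validate(
    analogues: Sequence[Analogue] | AnalogueSet,
    k: int = 10,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Leave-one-out validation of a read-across neighbourhood.

    Each analogue is predicted from the others via the similarity-
    weighted score (similarities recomputed between analogue
    fingerprints), and the AUROC of scores against true activities is
    reported with a seeded permutation p-value.  A single-class
    neighbourhood has no defined AUROC and is flagged ``undefined``
    rather than scored 0.
    """
    if isinstance(analogues, AnalogueSet):
        analogues = analogues.analogues
    n = len(analogues)
    if n < 2:
        raise ValueError("need at least 2 analogues for leave-one-out validation")
    acts = np.array([a.activity for a in analogues], dtype=float)
    if len(set(acts.tolist())) < 2:
        return {"auc": math.nan, "p_value": math.nan, "undefined": True,
                "reason": "single-class neighbourhood"}

    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = jaccard_similarity(
                analogues[i].fingerprint, analogues[j].fingerprint
            )

    def loo_scores(activities: np.ndarray) -> np.ndarray:
        scores = np.zeros(n)
        for i in range(n):
            others = [j for j in range(n) if j != i]
            order = sorted(others, key=lambda j: -S[i, j])[:k]
            sims = S[i, order]
            if sims.sum() == 0:
                scores[i] = activities[[j for j in range(n) if j != i]].mean()
            else:
                scores[i] = float((sims * activities[order]).sum() / sims.sum())
        return scores

    obs_scores = loo_scores(acts)
    labels = ["H" if a == 1 else "L" for a in acts]
    _, _, obs_auc = roc_auc(obs_scores, labels, positive="H")

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(acts)
        if len(set(perm.tolist())) < 2:
            continue
        perm_scores = loo_scores(perm)
        perm_labels = ["H" if a == 1 else "L" for a in perm]
        _, _, perm_auc = roc_auc(perm_scores, perm_labels, positive="H")
        if perm_auc >= obs_auc:
            exceed += 1
    p_value = (exceed + 1) / (n_permutations + 1)
    return {"auc": obs_auc, "p_value": p_value, "undefined": False, "n": n, "k": k}
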