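"""Inter-chain contact extraction and scoring.

A contact is an inter-chain residue pair whose anchor atoms (Cβ, or Cα
for glycine) are closer than a cutoff (8 Å by default).  Predicted
contacts come from integrating distogram mass below the cutoff and
keeping pairs above a probability threshold (0.8 by default).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from gapfold.predictor import Distogram, PredictionResult
from gapfold.structures_io import Complex
from gapfold.template_engine import MergedTarget

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 8.0  # Å, strict inequality
DEFAULT_CONTACT_THRESHOLD = 0.8
DEFAULT_MIN_CONTACTS = 3

ContactKey = tuple[tuple[str, int], tuple[str, int]]


def _canonical_key(a: tuple[str, int], b: tuple[str, int]) -> ContactKey:
    return (a, b) if a <= b else (b, a)


@dataclass
class ContactSet:
    """Unordered inter-chain residue pairs, optionally with probabilities."""

    contacts: dict[ContactKey, float | None]
    scope: str = "inter_chain_only"

    def __post_init__(self) -> None:
        canonical: dict[ContactKey, float | None] = {}
        for (a, b), prob in self.contacts.items():
            if a[0] == b[0]:
                raise ValueError(f"intra-chain pair {a}-{b} violates inter-chain scope")
            canonical[_canonical_key(a, b)] = prob
        self.contacts = canonical

    def __len__(self) -> int:
        return len(self.contacts)

    def __contains__(self, key: ContactKey) -> bool:
        return _canonical_key(*key) in self.contacts

    @property
    def keys(self) -> set[ContactKey]:
        return set(self.contacts)

    @property
    def chain_names(self) -> set[str]:
        return {name for pair in self.contacts for name, _ in pair}

    def per_interface_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for (a, b) in self.contacts:
            key = f"{a[0]}-{b[0]}" if a[0] <= b[0] else f"{b[0]}-{a[0]}"
            counts[key] = counts.get(key, 0) + 1
        return counts


@dataclass
class ContactMetrics:
    """Precision/recall/template-satisfaction of one predicted set.

    Fractions are ``None`` (with the matching flag set) when their
    denominator is empty, never silently 0.
    """

    precision: float | None
    recall: float | None
    template_satisfaction: float | None
    n_predicted: int
    n_reference: int
    n_template: int
    undefined_precision: bool = False
    undefined_recall: bool = False
    undefined_satisfaction: bool = False

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "template_satisfaction": self.template_satisfaction,
            "n_predicted": self.n_predicted,
            "n_reference": self.n_reference,
            "n_template": self.n_template,
        }


def bin_weights_below_cutoff(bin_edges: np.ndarray, cutoff: float, mode: str = "linear") -> np.ndarray:
    """Per-bin fraction counted as below ``cutoff``.

    Bins entirely below the cutoff contribute fully; the straddling bin
    contributes a linear fraction (``mode='linear'``) or nothing
    (``mode='whole_bin'``); the open lower bin counts fully once the
    cutoff reaches the first edge.
    """
    edges = np.asarray(bin_edges, dtype=np.float64)
    n_bins = len(edges) + 1
    weights = np.zeros(n_bins)
    if cutoff < edges[0]:
        warnings.warn(
            f"cutoff {cutoff} below first distogram edge {edges[0]}; "
            "contact probability comes from the open lower bin only",
            stacklevel=2,
        )
        weights[0] = 1.0
        return weights
    weights[0] = 1.0
    for b in range(1, n_bins - 1):
        lo, hi = edges[b - 1], edges[b]
        if hi <= cutoff:
            weights[b] = 1.0
        elif lo < cutoff < hi:
            weights[b] = (cutoff - lo) / (hi - lo) if mode == "linear" else 0.0
        else:
            weights[b] = 0.0
    if cutoff > edges[-1]:
        weights[-1] = 1.0  # open upper bin has no finite width to prorate
    return weights


def contact_probability(distogram: Distogram, cutoff: float = DEFAULT_CONTACT_CUTOFF, mode: str = "linear") -> np.ndarray:
    """Per-pair probability of the distance being below ``cutoff``.

    Sums full bins below the cutoff plus a linear fraction of the
    straddling bin; symmetric and in [0, 1].
    """
    weights = bin_weights_below_cutoff(distogram.bin_edges, cutoff, mode=mode)
    probs = np.tensordot(distogram.probs, weights, axes=([-1], [0]))
    return np.clip(probs, 0.0, 1.0)


def default_chain_names(n_chains: int) -> list[str]:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    if n_chains > len(alphabet):
        return [f"C{i}" for i in range(n_chains)]
    return list(alphabet[:n_chains])


def predicted_contacts(
    result: PredictionResult,
    merged: MergedTarget,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    chain_ids: list[str] | None = None,
) -> ContactSet:
    """Extract inter-chain contacts from a prediction's distogram.

    Keeps pairs from different chains with contact probability strictly
    greater than ``threshold``; residues are numbered 1-based within
    each chain.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if chain_ids is None:
        chain_ids = default_chain_names(merged.n_chains)
    if len(chain_ids) != merged.n_chains:
        raise ValueError("chain_ids length must equal the number of chains")
    probs = contact_probability(result.distogram, cutoff)
    chain_of = merged.chain_of_position
    offsets = merged.chain_offsets
    contacts: dict[ContactKey, float | None] = {}
    n = len(merged)
    iu, ju = np.triu_indices(n, k=1)
    inter = chain_of[iu] != chain_of[ju]
    hit = probs[iu, ju] > threshold
    for i, j in zip(iu[inter & hit], ju[inter & hit]):
        ci, cj = int(chain_of[i]), int(chain_of[j])
        key = _canonical_key(
            (chain_ids[ci], int(i - offsets[ci] + 1)),
            (chain_ids[cj], int(j - offsets[cj] + 1)),
        )
        contacts[key] = float(probs[i, j])
    return ContactSet(contacts=contacts)


def reference_contacts(complex: Complex, cutoff: float = DEFAULT_CONTACT_CUTOFF) -> ContactSet:
    """All inter-chain pairs with anchor-atom distance strictly < cutoff.

    Residues are identified by (chain_id, author residue number); no
    probabilities are attached.
    """
    if len(complex.chains) < 2:
        warnings.warn("single-chain complex has no inter-chain contacts", stacklevel=2)
        return ContactSet(contacts={})
    contacts: dict[ContactKey, float | None] = {}
    for ai in range(len(complex.chains)):
        for bi in range(ai + 1, len(complex.chains)):
            ca, cb = complex.chains[ai], complex.chains[bi]
            dist = np.linalg.norm(
                ca.cb_coords[:, None, :] - cb.cb_coords[None, :, :], axis=-1
            )
            for i, j in zip(*np.nonzero(dist < cutoff)):
                key = _canonical_key(
                    (ca.chain_id, ca.residue_numbers[int(i)]),
                    (cb.chain_id, cb.residue_numbers[int(j)]),
                )
                contacts[key] = None
    return ContactSet(contacts=contacts)


def score_contacts(
    predicted: ContactSet,
    reference: ContactSet,
    template: ContactSet | None = None,
) -> ContactMetrics:
    """Precision, recall and template satisfaction of a predicted set."""
    if template is None:
        template = ContactSet(contacts={})
    for other in (reference, template):
        if predicted.keys and other.keys and not (predicted.chain_names & other.chain_names):
            raise ValueError(
                f"chain-name mismatch between contact sets: "
                f"{sorted(predicted.chain_names)} vs {sorted(other.chain_names)}"
            )
    n_pred = len(predicted)
    n_ref = len(reference)
    n_tmpl = len(template)
    tp = len(predicted.keys & reference.keys)
    sat = len(predicted.keys & template.keys)
    precision = tp / n_pred if n_pred else None
    recall = tp / n_ref if n_ref else None
    satisfaction = sat / n_pred if n_pred else None
    return ContactMetrics(
        precision=precision,
        recall=recall,
        template_satisfaction=satisfaction,
        n_predicted=n_pred,
        n_reference=n_ref,
        n_template=n_tmpl,
        undefined_precision=n_pred == 0,
        undefined_recall=n_ref == 0,
        undefined_satisfaction=n_pred == 0,
    )


def classify_plausible(predicted: ContactSet, min_contacts: int = DEFAULT_MIN_CONTACTS) -> bool:
    """True iff the prediction has at least ``min_contacts`` inter-chain contacts."""
    if min_contacts < 1:
        raise ValueError("min_contacts must be >= 1")
    return len(predicted) >= min_contacts


def write_contact_tsv(
    contacts: ContactSet,
    path: str | Path,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write contacts as TSV: chain_a, resnum_a, aa_a, chain_b, resnum_b, aa_b, probability."""
    def aa(chain: str, resnum: int) -> str:
        if sequences and chain in sequences and 1 <= resnum <= len(sequences[chain]):
            return sequences[chain][resnum - 1]
        return "X"

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chain_a", "resnum_a", "aa_a", "chain_b", "resnum_b", "aa_b", "probability"])
        for (a, b), prob in sorted(contacts.contacts.items()):
            writer.writerow([
                a[0], a[1], aa(*a), b[0], b[1], aa(*b),
                "" if prob is None else f"{prob:.4f}",
            ])
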