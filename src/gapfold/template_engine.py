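"""Template handling: chain assignment, pseudo-chain merging, features, perturbation.

The core trick lives here: all target chains are concatenated into one
pseudo-chain whose residue indices jump by ``gap_size + 1`` at chain
boundaries, and template coordinates from *different* template chains
are mapped onto that pseudo-chain without any inter-chain masking, so
the template's interface geometry survives featurization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner
from scipy.spatial.transform import Rotation

from gapfold.structures_io import ChainRecord, Complex

logger = logging.getLogger(__name__)

DEFAULT_GAP_SIZE = 200

# Global-alignment scoring used for target/template matching.  Match 1,
# mismatch 0, affine gaps -0.5/-0.1; identity is normalized by the
# shorter sequence so fragments score high against full-length partners.
MATCH_SCORE = 1.0
MISMATCH_SCORE = 0.0
GAP_OPEN = -0.5
GAP_EXTEND = -0.1


@dataclass
class Assignment:
    """Greedy target-to-template-chain assignment result."""

    pairs: list[tuple[int, str, float]]  # (target_index, template_chain_id, identity)
    unmatched_targets: list[int]
    unmatched_template_chains: list[str]

    def chain_for_target(self, target_index: int) -> str | None:
        for t, cid, _ in self.pairs:
            if t == target_index:
                return cid
        return None

    def to_dict(self) -> dict:
        return {
            "pairs": [
                {"target_index": t, "template_chain": c, "identity": i}
                for t, c, i in self.pairs
            ],
            "unmatched_targets": list(self.unmatched_targets),
            "unmatched_template_chains": list(self.unmatched_template_chains),
        }


@dataclass
class MergedTarget:
    """The single pseudo-chain over all target chains.

    ``residue_index`` is 1-based, increments by 1 within a chain and
    jumps by ``gap_size + 1`` across chain boundaries; the merged
    sequence contains no physical gap residues.
    """

    sequence: str
    residue_index: np.ndarray  # (L,) int
    chain_of_position: np.ndarray  # (L,) int ordinal
    chain_lengths: list[int]
    gap_size: int = DEFAULT_GAP_SIZE

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        self.chain_of_position = np.asarray(self.chain_of_position, dtype=np.int64)
        if len(self.sequence) != sum(self.chain_lengths):
            raise ValueError("merged sequence length != sum of chain lengths")
        if len(self.residue_index) != len(self.sequence):
            raise ValueError("residue_index length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_chains(self) -> int:
        return len(self.chain_lengths)

    @property
    def chain_offsets(self) -> list[int]:
        """Merged-position offset of each chain's first residue."""
        offsets, total = [], 0
        for length in self.chain_lengths:
            offsets.append(total)
            total += length
        return offsets

    def chain_slice(self, k: int) -> slice:
        off = self.chain_offsets[k]
        return slice(off, off + self.chain_lengths[k])


@dataclass
class TemplateFeatures:
    """Template anchor coordinates laid out on merged positions."""

    positions: np.ndarray  # (L, 3), NaN where absent
    ca_positions: np.ndarray  # (L, 3), NaN where absent
    mask: np.ndarray  # (L,) bool
    template_sequence: str  # '-' at unmasked-off positions

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.ca_positions = np.asarray(self.ca_positions, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.positions) == len(self.mask) == len(self.template_sequence)):
            raise ValueError("template feature arrays disagree in length")
        if np.isnan(self.positions[self.mask]).any():
            raise ValueError("masked-true positions must carry coordinates")


@dataclass
class PerturbationSpec:
    """Per-chain random rigid-body perturbation bounds."""

    max_angle: float = 30.0  # degrees
    max_shift: float = 5.0  # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_angle < 0 or self.max_shift < 0:
            raise ValueError("perturbation bounds must be non-negative")

    def to_dict(self) -> dict:
        return {
            "max_angle_deg": self.max_angle,
            "max_shift_angstrom": self.max_shift,
            "seed": self.seed,
            "rotation_sampling": "axis uniform on sphere, angle Uniform(0, max)",
            "translation_sampling": "direction uniform on sphere, magnitude Uniform(0, max)",
        }


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _align(a: str, b: str):
    """Best global alignment of a onto b (blocks of aligned index ranges)."""
    return _make_aligner().align(a, b)[0]


# integer-scaled scores (x10) so the DP is exact
_I_MATCH, _I_MISMATCH, _I_OPEN, _I_EXT = 10, 0, -5, -1
_NEG = (-(10**9), -(10**9))


def _max_identities_global(a: str, b: str) -> int:
    """Identities in the best-scoring global alignment (affine gaps),
    maximizing the identity count among co-optimal alignments.

    Gotoh DP over (score, identities) tuples with integer scores, so the
    result is exact and symmetric in its arguments.
    """
    n, m = len(a), len(b)

    def add(state: tuple[int, int], score: int, ident: int = 0) -> tuple[int, int]:
        return (state[0] + score, state[1] + ident)

    # per-row states: M = a[i] aligned to b[j], X = gap in b, Y = gap in a
    prev_m = [_NEG] * (m + 1)
    prev_x = [_NEG] * (m + 1)
    prev_y = [_NEG] * (m + 1)
    prev_m[0] = (0, 0)
    for j in range(1, m + 1):
        prev_y[j] = (_I_OPEN + _I_EXT * (j - 1), 0)
    for i in range(1, n + 1):
        cur_m = [_NEG] * (m + 1)
        cur_x = [_NEG] * (m + 1)
        cur_y = [_NEG] * (m + 1)
        cur_x[0] = (_I_OPEN + _I_EXT * (i - 1), 0)
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = _I_MATCH if ai == b[j - 1] else _I_MISMATCH
            ident = 1 if ai == b[j - 1] else 0
            cur_m[j] = max(
                add(prev_m[j - 1], sub, ident),
                add(prev_x[j - 1], sub, ident),
                add(prev_y[j - 1], sub, ident),
            )
            cur_x[j] = max(
                add(prev_m[j], _I_OPEN),
                add(prev_x[j], _I_EXT),
                add(prev_y[j], _I_OPEN),
            )
            cur_y[j] = max(
                add(cur_m[j - 1], _I_OPEN),
                add(cur_y[j - 1], _I_EXT),
                add(cur_x[j - 1], _I_OPEN),
            )
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return max(prev_m[m], prev_x[m], prev_y[m])[1]


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical aligned positions over the shorter length.

    Uses a global alignment (match 1, mismatch 0, gap open/extend
    -0.5/-0.1), taking the maximal identity count among co-optimal
    alignments; symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return _max_identities_global(a, b) / min(len(a), len(b))


def assign_chains(targets: list[str], template: Complex) -> Assignment:
    """Greedily assign target sequences to template chains by identity.

    All (target, chain) pairs are scored; pairs are accepted in
    descending identity order, skipping any pair whose target or chain
    is already taken.  Ties break on lower target index, then
    lexicographic chain ID.
    """
    if not targets:
        raise ValueError("need at least one target sequence")
    scored = []
    for ti, tseq in enumerate(targets):
        for chain in template.chains:
            ident = sequence_identity(tseq, chain.sequence)
            scored.append((ti, chain.chain_id, ident))
    scored.sort(key=lambda rec: (-rec[2], rec[0], rec[1]))
    used_targets: set[int] = set()
    used_chains: set[str] = set()
    pairs: list[tuple[int, str, float]] = []
    for ti, cid, ident in scored:
        if ti in used_targets or cid in used_chains:
            continue
        pairs.append((ti, cid, ident))
        used_targets.add(ti)
        used_chains.add(cid)
    pairs.sort(key=lambda rec: rec[0])
    unmatched_targets = [t for t in range(len(targets)) if t not in used_targets]
    unmatched_chains = sorted(c.chain_id for c in template.chains if c.chain_id not in used_chains)
    if unmatched_chains:
        logger.warning("template chains without a target: %s (dropped)", unmatched_chains)
    if unmatched_targets:
        logger.warning("targets without a template chain: %s (proceed template-free)", unmatched_targets)
    return Assignment(pairs, unmatched_targets, unmatched_chains)


def merge_chains(targets: list[str], gap_size: int = DEFAULT_GAP_SIZE) -> MergedTarget:
    """Concatenate target chains into the gap-indexed pseudo-chain."""
    if not targets:
        raise ValueError("need at least one target sequence")
    if gap_size < 1:
        raise ValueError("gap_size must be >= 1")
    if any(not t for t in targets):
        raise ValueError("target sequences must be non-empty")
    sequence = "".join(targets)
    residue_index = np.empty(len(sequence), dtype=np.int64)
    chain_of_position = np.empty(len(sequence), dtype=np.int64)
    pos = 0
    next_index = 1
    for k, seq in enumerate(targets):
        for _ in seq:
            residue_index[pos] = next_index
            chain_of_position[pos] = k
            pos += 1
            next_index += 1
        next_index += gap_size  # boundary jump is gap_size + 1
    return MergedTarget(
        sequence=sequence,
        residue_index=residue_index,
        chain_of_position=chain_of_position,
        chain_lengths=[len(t) for t in targets],
        gap_size=gap_size,
    )


def build_template_features(
    merged: MergedTarget, assignment: Assignment, template: Complex
) -> TemplateFeatures:
    """Map template coordinates onto merged positions via pairwise alignment.

    Template chains keep their original relative geometry — coordinates
    from different chains land on the pseudo-chain untouched, which is
    what preserves (unmasks) the inter-chain interface information.
    Unassigned target chains get an all-false mask.
    """
    n = len(merged)
    positions = np.full((n, 3), np.nan)
    ca_positions = np.full((n, 3), np.nan)
    mask = np.zeros(n, dtype=bool)
    tseq_chars = ["-"] * n
    targets = [merged.sequence[merged.chain_slice(k)] for k in range(merged.n_chains)]
    template_ids = set(template.chain_ids)
    for target_index, chain_id, _ident in assignment.pairs:
        if chain_id not in template_ids:
            raise ValueError(f"assignment references unknown template chain {chain_id!r}")
        if target_index >= merged.n_chains:
            raise ValueError(f"assignment references unknown target index {target_index}")
        tchain = template.get_chain(chain_id)
        offset = merged.chain_offsets[target_index]
        aln = _align(targets[target_index], tchain.sequence)
        for (t_start, t_end), (c_start, c_end) in zip(*aln.aligned):
            for t_pos, c_pos in zip(range(t_start, t_end), range(c_start, c_end)):
                mpos = offset + t_pos
                positions[mpos] = tchain.cb_coords[c_pos]
                ca_positions[mpos] = tchain.ca_coords[c_pos]
                mask[mpos] = True
                tseq_chars[mpos] = tchain.sequence[c_pos]
    return TemplateFeatures(
        positions=positions,
        ca_positions=ca_positions,
        mask=mask,
        template_sequence="".join(tseq_chars),
    )


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    norm = np.linalg.norm(v)
    while norm < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
    return v / norm


def sample_rigid_transform(
    spec: PerturbationSpec, rng: np.random.Generator
) -> tuple[Rotation, np.ndarray, float, float]:
    """Draw one rigid transform: rotation axis uniform on the sphere with
    angle ~ U(0, max_angle); translation direction uniform with magnitude
    ~ U(0, max_shift).  Returns (rotation, translation, angle_deg, shift)."""
    axis = _random_unit_vector(rng)
    angle = rng.uniform(0.0, spec.max_angle)
    rot = Rotation.from_rotvec(axis * np.deg2rad(angle))
    direction = _random_unit_vector(rng)
    shift = rng.uniform(0.0, spec.max_shift)
    return rot, direction * shift, angle, shift


def perturb_template(template: Complex, spec: PerturbationSpec) -> Complex:
    """Rigid-body perturb each chain independently about its centre of mass.

    Intra-chain geometry is preserved exactly; results are deterministic
    for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    new_chains: list[ChainRecord] = []
    for chain in template.chains:
        rot, translation, angle, shift = sample_rigid_transform(spec, rng)
        com = chain.com
        cb = rot.apply(chain.cb_coords - com) + com + translation
        ca = rot.apply(chain.ca_coords - com) + com + translation
        logger.debug(
            "chain %s perturbed: angle %.2f deg, shift %.2f A", chain.chain_id, angle, shift
        )
        new_chains.append(
            ChainRecord(
                chain_id=chain.chain_id,
                sequence=chain.sequence,
                residue_numbers=list(chain.residue_numbers),
                cb_coords=cb,
                ca_coords=ca,
                com=com + translation,
            )
        )
    return Complex(chains=new_chains, source_format=template.source_format)
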