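"""Synthetic fixture generation: toy complexes, a3m fabrication.

Chains are built as ideal α-helices laid side by side, which gives a
dense, tunable inter-chain interface with an exactly known anchor-atom
contact map — everything the test surface and the mock backend need.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from gapfold.structures_io import ChainRecord, Complex, write_fasta, write_structure

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# ideal α-helix parameters
HELIX_RISE = 1.5  # Å per residue along the axis
HELIX_RADIUS = 2.3  # Å, Cα radius
HELIX_TURN = np.deg2rad(100.0)  # per residue
CB_OFFSET = 1.5  # Å further out radially for Cβ


def random_sequence(length: int, rng: np.random.Generator, glycine_every: int = 7) -> str:
    """Random sequence with periodic glycines (exercises the Cα fallback)."""
    chars = [AA20[i] for i in rng.integers(0, len(AA20), size=length)]
    for i in range(glycine_every - 1, length, glycine_every):
        chars[i] = "G"
    return "".join(chars)


def helix_chain(
    chain_id: str,
    sequence: str,
    origin: np.ndarray,
    axis_jitter: float = 0.0,
    rng: np.random.Generator | None = None,
    start_resnum: int = 1,
) -> ChainRecord:
    """Ideal helix along x starting at ``origin``; Cβ radially outward."""
    n = len(sequence)
    t = np.arange(n)
    ca = np.empty((n, 3))
    ca[:, 0] = origin[0] + HELIX_RISE * t
    ca[:, 1] = origin[1] + HELIX_RADIUS * np.cos(HELIX_TURN * t)
    ca[:, 2] = origin[2] + HELIX_RADIUS * np.sin(HELIX_TURN * t)
    radial = np.zeros((n, 3))
    radial[:, 1] = np.cos(HELIX_TURN * t)
    radial[:, 2] = np.sin(HELIX_TURN * t)
    cb = ca + CB_OFFSET * radial
    if axis_jitter > 0 and rng is not None:
        ca = ca + rng.normal(scale=axis_jitter, size=ca.shape)
        cb = cb + rng.normal(scale=axis_jitter, size=cb.shape)
    cb = np.where(np.array([aa == "G" for aa in sequence])[:, None], ca, cb)
    return ChainRecord(
        chain_id=chain_id,
        sequence=sequence,
        residue_numbers=list(range(start_resnum, start_resnum + n)),
        cb_coords=cb,
        ca_coords=ca,
        com=np.concatenate([ca, cb]).mean(axis=0),
    )


def make_complex(
    chain_lengths: list[int],
    seed: int = 0,
    spacing: float = 7.0,
    sequences: list[str] | None = None,
    chain_ids: list[str] | None = None,
) -> Complex:
    """Build a toy multi-chain complex of parallel helices.

    ``spacing`` is the inter-helix axis distance; ~7 Å gives a dense
    interface between neighbouring chains, larger values thin it out.
    """
    rng = np.random.default_rng(seed)
    n_chains = len(chain_lengths)
    if sequences is None:
        sequences = [random_sequence(length, rng) for length in chain_lengths]
    if chain_ids is None:
        chain_ids = [chr(ord("A") + i) for i in range(n_chains)]
    chains = []
    for k, (seq, cid) in enumerate(zip(sequences, chain_ids)):
        origin = np.array([0.0, spacing * k, 0.0])
        chains.append(helix_chain(cid, seq, origin))
    return Complex(chains=chains, source_format="pdb")


def mutate_sequence(sequence: str, rng: np.random.Generator, rate: float) -> str:
    chars = list(sequence)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = AA20[rng.integers(0, len(AA20))]
    return "".join(chars)


def make_a3m_text(
    query: str,
    n_rows: int,
    seed: int = 0,
    mutation_rate: float = 0.15,
    deletion_rate: float = 0.05,
    insertion_rate: float = 0.03,
) -> str:
    """Fabricate a3m text: query first, then mutated homolog rows with
    occasional '-' deletions and lowercase insertions."""
    rng = np.random.default_rng(seed)
    lines = [">query", query]
    for r in range(1, n_rows):
        row_chars = []
        for ch in query:
            if rng.random() < insertion_rate:
                row_chars.append(AA20[rng.integers(0, len(AA20))].lower())
            if rng.random() < deletion_rate:
                row_chars.append("-")
            elif rng.random() < mutation_rate:
                row_chars.append(AA20[rng.integers(0, len(AA20))])
            else:
                row_chars.append(ch)
        lines.append(f">homolog_{r}")
        lines.append("".join(row_chars))
    return "\n".join(lines) + "\n"


def write_fixture_set(
    output_dir: str | Path,
    chain_lengths: list[int] = (60, 55),
    seed: int = 0,
    spacing: float = 7.0,
    msa_rows: int = 8,
) -> dict:
    """Write a self-contained fixture set: template PDB + mmCIF, target
    FASTA, and one a3m per chain.  Returns the file map."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    complex = make_complex(list(chain_lengths), seed=seed, spacing=spacing)
    template_pdb = output_dir / "template.pdb"
    template_cif = output_dir / "template.cif"
    write_structure(complex, template_pdb, format="pdb")
    write_structure(complex, template_cif, format="mmcif")
    fasta_path = output_dir / "target.fasta"
    headers = [f"chain_{c.chain_id}" for c in complex.chains]
    write_fasta([(h, c.sequence) for h, c in zip(headers, complex.chains)], fasta_path)
    msa_dir = output_dir / "msas"
    msa_dir.mkdir(exist_ok=True)
    msa_files = []
    for i, (header, chain) in enumerate(zip(headers, complex.chains)):
        a3m_path = msa_dir / f"{header}.a3m"
        a3m_path.write_text(make_a3m_text(chain.sequence, msa_rows, seed=seed + i))
        msa_files.append(str(a3m_path))
    return {
        "template_pdb": str(template_pdb),
        "template_mmcif": str(template_cif),
        "fasta": str(fasta_path),
        "msa_dir": str(msa_dir),
        "msa_files": msa_files,
        "chain_lengths": list(chain_lengths),
        "seed": seed,
        "spacing": spacing,
    }
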