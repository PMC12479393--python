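"""Split merged predictions back into multi-chain models and rank them."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from gapfold.predictor import PredictionResult
from gapfold.structures_io import ChainRecord, Complex, write_structure
from gapfold.template_engine import MergedTarget

logger = logging.getLogger(__name__)


@dataclass
class RankedModel:
    complex: Complex
    ptm: float
    model_id: int
    rank: int  # 1 = best
    relaxed: bool = False


def split_merged(
    result: PredictionResult, merged: MergedTarget, chain_ids: list[str]
) -> Complex:
    """Partition merged-position coordinates back into chains.

    Chain boundaries come from the stored chain-of-position map (never
    inferred from residue-index jumps); each chain is renumbered 1..L
    and chains keep the input order.
    """
    if len(chain_ids) != merged.n_chains:
        raise ValueError(
            f"{len(chain_ids)} chain IDs for {merged.n_chains} chains"
        )
    ca = result.coords["CA"]
    cb = result.coords["CB"]
    if len(ca) != len(merged) or len(cb) != len(merged):
        raise ValueError("coordinate count does not match merged target length")
    chains = []
    for k in range(merged.n_chains):
        sl = merged.chain_slice(k)
        seq = merged.sequence[sl]
        chains.append(
            ChainRecord(
                chain_id=chain_ids[k],
                sequence=seq,
                residue_numbers=list(range(1, len(seq) + 1)),
                cb_coords=cb[sl].copy(),
                ca_coords=ca[sl].copy(),
            )
        )
    return Complex(chains=chains, source_format="pdb")


def rank_models(
    results: list[PredictionResult], merged: MergedTarget, chain_ids: list[str]
) -> list[RankedModel]:
    """Rank predictions by pTM (descending), ties to the lower model ID.

    The rank-1 model is the one flagged for relaxation when a real
    backend provides it; here its ``relaxed`` flag simply mirrors the
    backend's output.
    """
    if not results:
        raise ValueError("no prediction results to rank")
    ordered = sorted(results, key=lambda r: (-r.ptm, r.model_id))
    ranked = []
    for rank, result in enumerate(ordered, start=1):
        ranked.append(
            RankedModel(
                complex=split_merged(result, merged, chain_ids),
                ptm=result.ptm,
                model_id=result.model_id,
                rank=rank,
                relaxed=result.relaxed,
            )
        )
    return ranked


def write_models(ranked: list[RankedModel], output_dir: str | Path) -> dict:
    """Write each ranked model as PDB + mmCIF and return the ranking table."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    table = []
    for model in ranked:
        stem = f"model_rank{model.rank}_net{model.model_id}"
        pdb_path = output_dir / f"{stem}.pdb"
        cif_path = output_dir / f"{stem}.cif"
        write_structure(model.complex, pdb_path, format="pdb")
        write_structure(model.complex, cif_path, format="mmcif")
        table.append(
            {
                "rank": model.rank,
                "model_id": model.model_id,
                "ptm": model.ptm,
                "relaxed": model.relaxed,
                "pdb": pdb_path.name,
                "mmcif": cif_path.name,
            }
        )
    with open(output_dir / "ranking.json", "w") as fh:
        json.dump({"models": table}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"models": table}
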