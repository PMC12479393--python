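# gapfold

Multimeric protein-complex prediction through a single merged
pseudo-chain. All target chains are concatenated into one chain whose
residue indices jump by a large constant (200 by default) at chain
boundaries, so a monomer-trained structure-prediction network sees the
assembly as a single protein while the multimeric template keeps its
inter-chain geometry (no inter-chain masking). The neural-network step
is a pluggable backend: an adapter stub for a real AlphaFold2
installation, and a deterministic mock backend that fabricates
network outputs (distogram, coordinates, pTM) consistent with a known
ground-truth structure so the entire pipeline is testable offline on a
CPU.

What is implemented here, fully and verifiably:

- **structures_io** — PDB/mmCIF/FASTA I/O; per-residue anchor atoms
  (Cβ, with Cα standing in at glycines and Cβ-less residues).
- **template_engine** — greedy target↔template chain assignment by
  global-alignment sequence identity; pseudo-chain merging with
  residue-index gaps; template feature construction that preserves
  inter-chain geometry; random per-chain rigid-body template
  perturbation (`--rotrans`).
- **msa_engine** — a3m parsing and unpaired block-diagonal MSA merging
  over the merged query.
- **predictor** — the backend contract (validated at the boundary:
  distogram symmetry/normalization, coordinate coverage), the mock
  backend, and the AF2 adapter stub.
- **contact_analysis** — distogram→contact-probability integration
  (full bins below the cutoff plus a linear fraction of the straddling
  bin), inter-chain contact extraction above a probability threshold
  (default 0.8, cutoff 8 Å), reference contacts from coordinates,
  precision/recall/template-satisfaction metrics, and the
  contact-count plausibility classifier (default ≥ 3 contacts).
- **assembly** — splitting merged predictions back into chains,
  pTM ranking, model/report writing.
- **fixtures** — synthetic data generation (toy helix-bundle complexes
  with known contact maps, fabricated a3m files).

## CLI

```sh
# generate a self-contained synthetic input set
gapfold fixtures --output-dir demo --chain-lengths 60,55 --seed 0

# full pipeline with the mock backend (deterministic given --seed)
gapfold predict \
    --fasta demo/target.fasta \
    --template demo/template.pdb \
    --msa-dir demo/msas \
    --output-dir demo/run \
    --rotrans 30,5 --seed 7

# outputs: ranked models (PDB + mmCIF), ranking.json, contacts.tsv,
# contacts_summary.json, assignment.json, merged.a3m, manifest.json

# perturb a template only
gapfold perturb --template demo/template.pdb --out perturbed.pdb --rotrans 30,5

# score one structure's inter-chain contacts against a reference
gapfold contacts --model demo/run/model_rank1_net1.pdb --reference demo/template.pdb
```

`gapfold predict --help` documents all options, including the backend
selection (`--backend mock|alphafold2`), mock-backend controls
(`--mock-truth`, `--mock-noise`, `--mock-ptm`) and a JSON config file
(`--config`, overridden by explicit flags). Runs with identical config
and seed produce byte-identical manifests and (mock backend) models.

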