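"""Seeded generator of two-layer symptom-disease networks with planted comorbidity.

The generator emulates the structure of a real symptom-disease resource
without any downloads. Diseases are partitioned into co-occurrence modules
(every within-module pair co-occurs). The co-occurrence signal is planted
through BOTH layers:

* shared proteins — each module owns a block of proteins; a member disease
  carries each module protein with probability ``protein_sharing_rate``
  against a low background rate, and the disease intra-layer block is the
  pairwise Tanimoto similarity of the resulting protein bit profiles, so
  module partners are more similar than strangers;
* shared symptoms — each module owns a block of symptoms; a disease links to
  each module symptom with probability ``within_module_symptom_overlap``
  against ``background_symptom_rate`` elsewhere, all links independent
  Bernoulli. The binary disease x symptom matrix is the inter-layer block.

Planting through both routes means the single-layer (disease-only) baseline
already ranks module partners above chance and the symptom layer adds
further signal — the qualitative ordering the method is built to exploit.
All inter-layer links being independent Bernoulli also makes
``within_module_symptom_overlap == background_symptom_rate`` an exact null:
the network then carries no symptom signal at all, which is what calibration
of the enrichment test requires.

The symptom intra-layer block is the pairwise Tanimoto similarity of
symptom x disease incidence bit vectors (symptoms are similar when the same
diseases accompany them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .comorbidity import CooccurrenceTable
from .kernels import BitProfileMatrix, pairwise_tanimoto
from .network import Layer, MultiLayerNetwork


@dataclass
class GeneratorConfig:
    """Synthetic two-layer network parameters.

    Defaults give a desk-scale network (200 diseases in 20 ten-disease
    modules, 60 symptoms, 300 proteins) with strong planted signal.
    """

    n_diseases: int = 200
    n_symptoms: int = 60
    n_proteins: int = 300
    n_modules: int = 20
    within_module_symptom_overlap: float = 0.4
    background_symptom_rate: float = 0.02
    protein_sharing_rate: float = 0.12
    background_protein_rate: float = 0.02
    seed: int = 0
    disease_layer: str = "disease"
    symptom_layer: str = "symptom"

    def __post_init__(self) -> None:
        for p in (
            self.within_module_symptom_overlap,
            self.background_symptom_rate,
            self.protein_sharing_rate,
            self.background_protein_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for c in (self.n_diseases, self.n_symptoms, self.n_proteins, self.n_modules):
            if c < 1:
                raise ValueError("counts must be >= 1")
        if self.n_modules > self.n_diseases:
            raise ValueError("n_modules cannot exceed n_diseases")


def _module_assignment(n_items: int, n_modules: int) -> np.ndarray:
    """Contiguous, balanced assignment of items to modules."""
    return np.repeat(
        np.arange(n_modules),
        np.diff(np.linspace(0, n_items, n_modules + 1).round().astype(int)),
    )


def generate(
    config: GeneratorConfig,
) -> tuple[MultiLayerNetwork, CooccurrenceTable, BitProfileMatrix]:
    """Generate a two-layer network, its planted co-occurrence table, and the
    disease x protein ground-truth profiles. Fully reproducible from the seed."""
    root = np.random.SeedSequence(config.seed)
    rng_prot, rng_sympt = (np.random.default_rng(s) for s in root.spawn(2))

    d_ids = tuple(f"D{i:04d}" for i in range(config.n_diseases))
    s_ids = tuple(f"S{i:04d}" for i in range(config.n_symptoms))
    p_ids = tuple(f"P{i:04d}" for i in range(config.n_proteins))

    module_of_disease = _module_assignment(config.n_diseases, config.n_modules)
    module_of_protein = _module_assignment(config.n_proteins, config.n_modules)
    module_of_symptom = _module_assignment(config.n_symptoms, config.n_modules)

    # disease x protein incidence: elevated rate on the module's own proteins
    prot_rate = np.full((config.n_diseases, config.n_proteins), config.background_protein_rate)
    same_module = module_of_disease[:, None] == module_of_protein[None, :]
    prot_rate[same_module] = config.protein_sharing_rate
    profiles = (rng_prot.random(prot_rate.shape) < prot_rate).astype(np.int8)
    profile_matrix = BitProfileMatrix(d_ids, p_ids, profiles)
    w_disease = pairwise_tanimoto(profile_matrix)

    # disease x symptom incidence: independent Bernoulli per pair
    sympt_rate = np.full((config.n_diseases, config.n_symptoms), config.background_symptom_rate)
    same_module = module_of_disease[:, None] == module_of_symptom[None, :]
    sympt_rate[same_module] = config.within_module_symptom_overlap
    inter = (rng_sympt.random(sympt_rate.shape) < sympt_rate).astype(float)

    # symptom similarity from symptom x disease incidence bit vectors
    w_symptom = pairwise_tanimoto(inter.T.astype(np.int8))

    network = MultiLayerNetwork(
        layers=[Layer(config.disease_layer, d_ids), Layer(config.symptom_layer, s_ids)],
        intra_blocks=[w_disease, w_symptom],
        inter_blocks=[inter],
    )
    pairs = [
        (d_ids[i], d_ids[j])
        for i in range(config.n_diseases)
        for j in range(i + 1, config.n_diseases)
        if module_of_disease[i] == module_of_disease[j]
    ]
    return network, CooccurrenceTable(pairs), profile_matrix


def export(
    network: MultiLayerNetwork,
    cooccurrence: CooccurrenceTable,
    directory: str | Path,
) -> dict[str, Path]:
    """Write the network and co-occurrence table in the package's text formats.

    Emits nodes.tsv, intra_edges.tsv, inter_edges.tsv and cooccurrence.tsv;
    a round-trip load reproduces the in-memory weight matrices bitwise.
    """
    from . import io as lio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = lio.write_network(network, directory)
    paths["cooccurrence"] = lio.write_cooccurrence(
        cooccurrence, directory / "cooccurrence.tsv"
    )
    return paths
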