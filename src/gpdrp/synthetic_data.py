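"""Synthetic fixtures: drug panels, pathway scores, planted-signal responses.

Everything the model consumes can be generated here without downloads, at
the axis sizes of a real drug screen (a 173-compound panel, a 1329 × 550
GSVA-style score matrix, a 54-sample xenograft set) or smaller.  Drugs are
built by decorating drug-like ring scaffolds with substituent fragments, so
every SMILES is chemically valid by construction.  Responses carry a planted
signal that is computable from features the model can see — a graph
descriptor per drug and a sparse linear read-out of pathway rows per cell
line — which makes signal-recovery tests fair and gives a closed-form
linear oracle to compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .analysis import PredictionMatrix
from .drug_graph import AtomFeatureSchema, smiles_to_graph
from .pathway_features import PathwayScoreMatrix
from .response_scaling import ResponseTable

# ring scaffolds with one or two substitution slots ({}), drug-like cores
_SCAFFOLDS: tuple[str, ...] = (
    "c1ccc({})cc1",
    "c1ccc2cc({})ccc2c1",
    "c1ccnc({})c1",
    "c1cnc({})nc1",
    "c1ccc(-c2ccc({})cc2)cc1",
    "C1CCN({})CC1",
    "C1CCC({})CC1",
    "O=C(N{})c1ccccc1",
    "c1ccc(O{})cc1",
    "c1ccc(S(=O)(=O)N{})cc1",
    "c1cc({})ccc1{}",
    "c1ccc(C(=O)O{})cc1",
    "c1cc({})cnc1{}",
)

_SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CO", "CCO", "Cl", "F", "Br", "OC",
    "N", "C#N", "C(F)(F)F", "C(=O)O", "C(=O)N", "N1CCOCC1",
    "S(=O)(=O)C", "CCN(C)C", "C=C", "CNC",
)


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic drug-response dataset."""

    n_drugs: int = 60
    n_cell_lines: int = 80
    n_pathways: int = 200
    latent_rank: int = 10
    noise_sd: float = 0.5  # on the LN IC50 scale
    signal_coefficients: tuple[float, float, float] = (1.0, 1.0, 0.5)
    missing_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if min(self.n_drugs, self.n_cell_lines, self.n_pathways) < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted signal saved at generation time for recovery tests."""

    delta: pd.Series  # standardized graph descriptor per drug
    pi: pd.Series  # standardized pathway read-out per cell line
    coefficients: tuple[float, float, float]
    noise_sd: float
    pathway_subset: list[str]
    pathway_weights: np.ndarray
    masked_pairs: pd.DataFrame  # the unlabeled (drug, cell line) pairs


def _enumerate_panel() -> list[str]:
    """All valid, canonically-unique scaffold decorations, in a fixed order."""
    candidates: list[str] = []
    for scaffold in _SCAFFOLDS:
        n_slots = scaffold.count("{}")
        if n_slots == 1:
            candidates.extend(scaffold.format(s) for s in _SUBSTITUENTS)
        else:
            candidates.extend(
                scaffold.format(s1, s2) for s1 in _SUBSTITUENTS for s2 in _SUBSTITUENTS
            )
    seen: set[str] = set()
    panel: list[str] = []
    for smi in candidates:
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() == 0:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon not in seen:
            seen.add(canon)
            panel.append(smi)
    return panel


def generate_drug_panel(n: int, seed: int = 0) -> list[tuple[str, str]]:
    """n distinct, parseable drug-like SMILES, deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    panel = _enumerate_panel()
    if n > len(panel):
        raise ValueError(
            f"requested {n} drugs but the scaffold library caps at {len(panel)} distinct molecules"
        )
    rng = np.random.default_rng(seed)
    chosen = [panel[i] for i in rng.permutation(len(panel))[:n]]
    return [(f"drug_{i:03d}", smi) for i, smi in enumerate(chosen)]


def generate_pathway_matrix(
    n_pathways: int,
    n_cell_lines: int,
    latent_rank: int,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> PathwayScoreMatrix:
    """Low-rank factor product + Gaussian noise, clipped to [-1, 1].

    The factor scaling bounds the noiseless product inside [-1, 1], mimicking
    GSVA's bounded scores while keeping the correlated low-rank structure.
    """
    if not 0 <= latent_rank <= min(n_pathways, n_cell_lines):
        raise ValueError("latent_rank must be in [0, min(n_pathways, n_cell_lines)]")
    rng = np.random.default_rng(seed)
    if latent_rank == 0:
        values = np.zeros((n_pathways, n_cell_lines))
    else:
        scale = 1.0 / np.sqrt(latent_rank)
        U = rng.uniform(-scale, scale, size=(n_pathways, latent_rank))
        V = rng.uniform(-scale, scale, size=(latent_rank, n_cell_lines))
        values = U @ V
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, -1.0, 1.0)
    return PathwayScoreMatrix(
        values=values,
        pathway_ids=[f"PW_{i:04d}" for i in range(n_pathways)],
        cell_line_ids=[f"cell_{j:03d}" for j in range(n_cell_lines)],
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def drug_descriptor(smiles: str, schema: AtomFeatureSchema | None = None) -> float:
    """Raw graph descriptor: aromatic-atom fraction + heavy-atom count / 50."""
    g = smiles_to_graph(smiles, schema)
    aromatic_fraction = float(g.node_features[:, -1].mean())
    return aromatic_fraction + g.n_atoms / 50.0


def generate_responses(
    drug_panel: list[tuple[str, str]],
    pathway_matrix: PathwayScoreMatrix,
    spec: SyntheticSpec,
) -> tuple[ResponseTable, GroundTruth]:
    """Planted-signal LN IC50 for every drug × cell-line pair.

    ln_ic50(d, c) = a·δ(d) + b·π(c) + c·δ(d)·π(c) + ε,  ε ~ N(0, noise_sd²),
    with δ a standardized graph descriptor and π a standardized weighted sum
    of a sparse pathway subset.  A ``missing_fraction`` of pairs is masked
    (NaN), emulating a screen with unmeasured pairs.
    """
    if not drug_panel or not pathway_matrix.pathway_ids:
        raise ValueError("empty drug panel or pathway matrix")
    rng = np.random.default_rng(spec.seed + 1)
    drug_ids = [d for d, _ in drug_panel]
    delta = _standardize(np.array([drug_descriptor(smi) for _, smi in drug_panel]))

    n_subset = min(10, len(pathway_matrix.pathway_ids))
    subset_idx = np.sort(rng.choice(len(pathway_matrix.pathway_ids), n_subset, replace=False))
    weights = rng.normal(0.0, 1.0, size=n_subset)
    pi = _standardize(weights @ pathway_matrix.values[subset_idx, :])

    a, b, c = spec.signal_coefficients
    cells = pathway_matrix.cell_line_ids
    D, C = np.meshgrid(np.arange(len(drug_ids)), np.arange(len(cells)), indexing="ij")
    signal = a * delta[D] + b * pi[C] + c * delta[D] * pi[C]
    noise = rng.normal(0.0, spec.noise_sd, size=signal.shape) if spec.noise_sd > 0 else 0.0
    ln = (signal + noise).ravel()

    records = pd.DataFrame(
        {
            "drug_id": np.repeat(drug_ids, len(cells)),
            "cell_line_id": np.tile(cells, len(drug_ids)),
            "ln_ic50": ln,
        }
    )
    n_mask = round(spec.missing_fraction * len(records))
    mask_idx = rng.permutation(len(records))[:n_mask]
    records.loc[records.index[mask_idx], "ln_ic50"] = np.nan
    truth = GroundTruth(
        delta=pd.Series(delta, index=drug_ids, name="delta"),
        pi=pd.Series(pi, index=cells, name="pi"),
        coefficients=(a, b, c),
        noise_sd=spec.noise_sd,
        pathway_subset=[pathway_matrix.pathway_ids[i] for i in subset_idx],
        pathway_weights=weights,
        masked_pairs=records.loc[records["ln_ic50"].isna(), ["drug_id", "cell_line_id"]].reset_index(
            drop=True
        ),
    )
    return ResponseTable(records), truth


def generate_dataset(spec: SyntheticSpec):
    """One-call bundle: (drug panel, raw score matrix, responses, truth)."""
    drugs = generate_drug_panel(spec.n_drugs, seed=spec.seed)
    scores = generate_pathway_matrix(
        spec.n_pathways, spec.n_cell_lines, spec.latent_rank, seed=spec.seed
    )
    responses, truth = generate_responses(drugs, scores, spec)
    return drugs, scores, responses, truth


def linear_oracle_pcc(
    truth: GroundTruth,
    responses: ResponseTable,
    train_cells: list[str],
    test_cells: list[str],
) -> float:
    """Held-out Pearson r of least squares on the planted features (δ, π, δπ).

    The oracle sees the ground-truth features directly, so its held-out
    correlation is an upper reference for what any model that must *learn*
    those features from graphs and pathway vectors can achieve.
    """
    lab = responses.labeled
    X_full = np.column_stack(
        [
            truth.delta[lab["drug_id"]].to_numpy(),
            truth.pi[lab["cell_line_id"]].to_numpy(),
            truth.delta[lab["drug_id"]].to_numpy() * truth.pi[lab["cell_line_id"]].to_numpy(),
            np.ones(len(lab)),
        ]
    )
    y = lab["ln_ic50"].to_numpy()
    in_train = lab["cell_line_id"].isin(set(train_cells)).to_numpy()
    in_test = lab["cell_line_id"].isin(set(test_cells)).to_numpy()
    beta, *_ = np.linalg.lstsq(X_full[in_train], y[in_train], rcond=None)
    pred = X_full[in_test] @ beta
    from .model import pearson

    return pearson(y[in_test], pred)


# ---------------------------------------------------------------------------
# Xenograft-style fixture
# ---------------------------------------------------------------------------

DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("PRE-CX", 9),
    ("POST-CX", 8),
    ("CRPC", 10),
    ("ENZS", 12),
    ("ENZR", 15),
)

N_PROLIFERATION_PATHWAYS = 12


@dataclass
class XenograftFixture:
    samples: pd.DataFrame  # sample_id, group, planted_cluster
    scores: PathwayScoreMatrix  # pathways × samples, incl. PROLIF_* block
    predictions: PredictionMatrix  # samples × drugs, LN scale
    separation: float = 2.0
    cluster_response_shifts: tuple[float, float, float] = (1.5, 0.0, -1.5)


def generate_xenograft_fixture(
    group_sizes: tuple[tuple[str, int], ...] | list[int] = DEFAULT_GROUPS,
    seed: int = 0,
    n_pathways: int = 60,
    n_drugs: int = 30,
    separation: float = 2.0,
    noise_sd: float = 0.15,
) -> XenograftFixture:
    """Samples with a planted 3-cluster structure.

    Each sample gets a pathway-score vector whose proliferation block
    (``PROLIF_01`` … ``PROLIF_12``) is shifted by its latent cluster, and a
    predicted-response row whose mean tracks the cluster (cluster 1 most
    resistant).  Group labels follow the xenograft screen layout (pre/post
    castration, castration-resistant, treatment-sensitive/-resistant) but
    clusters cut across groups, as they do in real data.
    """
    if isinstance(group_sizes, (list, tuple)) and group_sizes and not isinstance(group_sizes[0], tuple):
        group_sizes = tuple((f"group_{i}", int(n)) for i, n in enumerate(group_sizes))
    if not group_sizes:
        raise ValueError("group list must be non-empty")
    if any(n < 1 for _, n in group_sizes):
        raise ValueError("group sizes must be >= 1")
    if n_pathways < N_PROLIFERATION_PATHWAYS:
        raise ValueError(f"need at least {N_PROLIFERATION_PATHWAYS} pathways")
    rng = np.random.default_rng(seed)
    sample_ids, groups = [], []
    for gname, n in group_sizes:
        for i in range(n):
            sample_ids.append(f"{gname}_{i + 1:02d}")
            groups.append(gname)
    n_samples = len(sample_ids)
    clusters = rng.integers(1, 4, size=n_samples) if n_samples >= 3 else np.ones(n_samples, int)
    # guarantee all three clusters occur when there is room
    if n_samples >= 3:
        clusters[:3] = [1, 2, 3]

    prolif_ids = [f"PROLIF_{i + 1:02d}" for i in range(N_PROLIFERATION_PATHWAYS)]
    other_ids = [f"PW_{i:04d}" for i in range(n_pathways - N_PROLIFERATION_PATHWAYS)]
    pathway_ids = prolif_ids + other_ids
    values = rng.normal(0.0, noise_sd, size=(n_pathways, n_samples))
    # cluster 1 (resistant) gets the lowest proliferation activity
    prolif_shift = {1: -separation, 2: 0.0, 3: separation}
    for j, c in enumerate(clusters):
        values[:N_PROLIFERATION_PATHWAYS, j] += prolif_shift[int(c)]
    scores = PathwayScoreMatrix(values=values, pathway_ids=pathway_ids, cell_line_ids=sample_ids)

    response_shift = {1: 1.5, 2: 0.0, 3: -1.5}  # LN IC50: resistant = high
    drug_effect = rng.normal(0.0, 0.5, size=n_drugs)
    pred = np.empty((n_samples, n_drugs))
    for j, c in enumerate(clusters):
        pred[j] = response_shift[int(c)] + drug_effect + rng.normal(0.0, noise_sd, size=n_drugs)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "planted_cluster": clusters.astype(int)}
    )
    predictions = PredictionMatrix(
        values=pred,
        sample_ids=sample_ids,
        drug_ids=[f"drug_{i:03d}" for i in range(n_drugs)],
        metadata=samples.set_index("sample_id"),
    )
    return XenograftFixture(
        samples=samples, scores=scores, predictions=predictions, separation=separation
    )
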