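"""The GPDRP regressor: fusion head, training loop, splitting and metrics.

A drug-cell-line pair is encoded by the drug-graph branch and the pathway
DNN branch (128 dims each), concatenated into a 256-vector, and passed
through two fully connected layers (1024 and 128 units) to a single output
squashed onto (0, 1) — the scale of the transformed response.  Training
minimises mean squared error with Adam; model selection is early stopping
on validation RMSE.  Splitting is grouped by cell line so no cell line ever
appears in two partitions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .drug_graph import AtomFeatureSchema, MolecularGraph, smiles_to_graph
from .encoders import CellLineEncoder, DrugEncoder, EncoderConfig, GraphBatch
from .nn import Adam, Linear, Module, Tensor, concat, gather
from .pathway_features import PathwayScoreMatrix
from .response_scaling import ResponseTable, scale_response, unscale_response

logger = logging.getLogger(__name__)

PARTITIONS = ("train", "validation", "test")


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    fusion_dims: tuple[int, int] = (1024, 128)
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    loss: str = "mse"
    batch_size: int = 128
    max_epochs: int = 300
    patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.encoder, dict):
            self.encoder = EncoderConfig(**self.encoder)
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fusion_dims"] = list(self.fusion_dims)
        return d


@dataclass
class SplitAssignment:
    """cell line → partition mapping; pairs inherit their cell line's group."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self):
        bad = {v for v in self.assignment.values()} - set(PARTITIONS)
        if bad:
            raise ValueError(f"unknown partition label(s) {bad}")

    def cell_lines(self, partition: str) -> list[str]:
        return [c for c, p in self.assignment.items() if p == partition]

    def check_disjoint(self) -> None:
        # dict keys are unique by construction; this guards deserialised data
        groups = [set(self.cell_lines(p)) for p in PARTITIONS]
        for i in range(3):
            for j in range(i + 1, 3):
                if groups[i] & groups[j]:
                    raise AssertionError("cell line present in two partitions")


def split_by_cellline(
    cell_line_ids: list[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Deterministic grouped split: train/validation/test by cell line.

    Validation and test sizes are the rounded fractions; the remainder goes
    to train, so a 10-cell-line panel at (0.8, 0.1, 0.1) splits 8/1/1.
    """
    ids = list(cell_line_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell line ids")
    if len(ids) < 3:
        raise ValueError("need at least 3 cell lines to form 3 groups")
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n = len(ids)
    n_val = max(1, round(fractions[1] * n))
    n_test = max(1, round(fractions[2] * n))
    assignment: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_val:
            part = "validation"
        elif rank < n_val + n_test:
            part = "test"
        else:
            part = "train"
        assignment[ids[idx]] = part
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def rmse(actual, predicted) -> float:
    """Root mean squared error sqrt(mean((o_i − y_i)^2))."""
    a = np.asarray(actual, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    if a.size == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def pearson(actual, predicted) -> float:
    """Pearson correlation coefficient (covariance over the product of sds)."""
    a = np.asarray(actual, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if a.shape != p.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.std(a) == 0 or np.std(p) == 0:
        raise ValueError("Pearson correlation undefined for a constant input")
    return float(np.corrcoef(a, p)[0, 1])


@dataclass
class EvalReport:
    rmse: float
    pccs: float
    n_pairs: int
    scale: str  # "scaled" or "ln"

    def __post_init__(self):
        if self.rmse < 0 or not -1.0 <= self.pccs <= 1.0:
            raise ValueError("invalid metric values")


# ---------------------------------------------------------------------------
# Fusion head
# ---------------------------------------------------------------------------


class FusionHead(Module):
    """concat(drug, cell) → FC(1024) → FC(128) → 1, squashed onto (0, 1)."""

    def __init__(self, embed_dim: int, fusion_dims: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        d1, d2 = fusion_dims
        self.fc1 = self.add_child("fc1", Linear(2 * embed_dim, d1, rng))
        self.fc2 = self.add_child("fc2", Linear(d1, d2, rng))
        self.out = self.add_child("out", Linear(d2, 1, rng))

    def __call__(self, drug_emb: Tensor, cell_emb: Tensor) -> Tensor:
        if drug_emb.data.shape[1] != cell_emb.data.shape[1]:
            raise ValueError("drug and cell embeddings must have equal width")
        fused = concat([drug_emb, cell_emb], axis=-1)
        h = self.fc1(fused).relu()
        h = self.fc2(h).relu()
        return self.out(h).sigmoid()


def fuse_and_predict(drug_embedding, cell_embedding, head: FusionHead) -> float:
    """Score one pair from two 128-vectors through a fusion head."""
    d = np.atleast_2d(np.asarray(drug_embedding, dtype=np.float64))
    c = np.atleast_2d(np.asarray(cell_embedding, dtype=np.float64))
    if d.shape[1] != c.shape[1]:
        raise ValueError(f"embedding length mismatch: {d.shape[1]} vs {c.shape[1]}")
    return float(head(Tensor(d), Tensor(c)).data.ravel()[0])


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------


class GPDRP(Module):
    """End-to-end drug-response regressor over (molecular graph, pathway vector)."""

    def __init__(
        self,
        config: ModelConfig,
        schema: AtomFeatureSchema,
        pathway_ids: list[str],
    ):
        super().__init__()
        self.config = config
        self.schema = schema
        self.pathway_ids = list(pathway_ids)
        rng = np.random.default_rng(config.seed)
        self.drug_encoder = self.add_child(
            "drug_encoder", DrugEncoder(schema.total_dim, config.encoder, rng)
        )
        self.cell_encoder = self.add_child(
            "cell_encoder",
            CellLineEncoder(len(pathway_ids), rng, dropout=config.encoder.dropout),
        )
        self.head = self.add_child(
            "head", FusionHead(config.encoder.embed_dim, config.fusion_dims, rng)
        )

    # -- forward -------------------------------------------------------

    def forward_pairs(
        self,
        batch: GraphBatch,
        cell_features: np.ndarray,
        drug_idx: np.ndarray,
        cell_idx: np.ndarray,
    ) -> Tensor:
        """Predict scaled responses for index pairs into a drug batch and a
        cell-feature matrix.  Embeddings are computed once per unique drug /
        cell and gathered per pair."""
        drug_emb = self.drug_encoder(batch)
        cell_emb = self.cell_encoder(Tensor(cell_features))
        return self.head(gather(drug_emb, drug_idx), gather(cell_emb, cell_idx))

    # -- training ------------------------------------------------------

    def fit(
        self,
        drugs: list[tuple[str, str]],
        scores: PathwayScoreMatrix,
        responses: ResponseTable,
        split: SplitAssignment,
    ) -> pd.DataFrame:
        """Train on the labeled pairs of the train partition; early-stop on
        validation RMSE.  Returns the per-epoch history frame."""
        if not scores.normalized:
            raise ValueError("pathway scores must be normalized before training")
        if scores.pathway_ids != self.pathway_ids:
            raise ValueError("pathway axis differs from the model's recorded axis")
        split.check_disjoint()

        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)

        drug_ids = [d for d, _ in drugs]
        graphs = [smiles_to_graph(s, self.schema) for _, s in drugs]
        pe_dim = cfg.encoder.pe_dim if cfg.encoder.variant == "GIN_TRANSFORMER" else None
        batch_all = GraphBatch.from_graphs(graphs, pe_dim=pe_dim)
        cell_ids = scores.cell_line_ids
        feats = scores.values.T.copy()  # cell lines × pathways

        d_index = {d: i for i, d in enumerate(drug_ids)}
        c_index = {c: i for i, c in enumerate(cell_ids)}

        scaled = responses if responses.scaled else responses.scale()
        lab = scaled.labeled
        part = lab["cell_line_id"].map(split.assignment)
        if part.isna().any():
            missing = sorted(lab["cell_line_id"][part.isna()].unique())
            raise ValueError(f"cell line(s) missing from split: {missing}")

        def pack(frame: pd.DataFrame):
            return (
                frame["drug_id"].map(d_index).to_numpy(dtype=np.intp),
                frame["cell_line_id"].map(c_index).to_numpy(dtype=np.intp),
                frame["ln_ic50"].to_numpy(dtype=np.float64),
            )

        tr = pack(lab[part == "train"])
        va = pack(lab[part == "validation"])
        if tr[0].size == 0:
            raise ValueError("empty training partition")

        opt = Adam(self.parameters(), lr=cfg.learning_rate)
        history = []
        best = {"epoch": -1, "val_rmse": np.inf, "state": None}
        n_train = tr[0].size

        for epoch in range(cfg.max_epochs):
            self.train(True)
            order = rng.permutation(n_train)
            epoch_loss = 0.0
            for start in range(0, n_train, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                di, ci, y = tr[0][idx], tr[1][idx], tr[2][idx]
                pred = self.forward_pairs(batch_all, feats, di, ci)
                err = pred - Tensor(y[:, None])
                loss = (err**2).mean()
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"non-finite training loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * idx.size
            epoch_loss /= n_train

            val_rmse = val_pcc = np.nan
            if va[0].size:
                pv = self._predict_indices(batch_all, feats, va[0], va[1])
                val_rmse = rmse(va[2], pv)
                val_pcc = pearson(va[2], pv) if np.std(pv) > 0 and va[2].size > 1 else np.nan
            history.append(
                {"epoch": epoch, "train_loss": epoch_loss, "val_rmse": val_rmse, "val_pcc": val_pcc}
            )
            logger.info("epoch %d loss %.5f val_rmse %s", epoch, epoch_loss, val_rmse)

            monitor = val_rmse if va[0].size else epoch_loss
            if monitor < best["val_rmse"] - 1e-7:
                best = {
                    "epoch": epoch,
                    "val_rmse": monitor,
                    "state": {k: v.copy() for k, v in self.state_arrays().items()},
                }
            elif epoch - best["epoch"] >= cfg.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best["epoch"])
                break

        if best["state"] is not None:
            self.load_state_arrays(best["state"])
        self.eval()
        self._train_artifacts = {
            "drugs": drugs,
            "batch": batch_all,
            "feats": feats,
            "d_index": d_index,
            "c_index": c_index,
            "best_epoch": best["epoch"],
        }
        return pd.DataFrame(history)

    def _predict_indices(self, batch, feats, di, ci) -> np.ndarray:
        self.eval()
        return self.forward_pairs(batch, feats, di, ci).data.ravel()

    # -- prediction ----------------------------------------------------

    def predict_pairs(
        self,
        drugs: list[tuple[str, str]],
        scores: PathwayScoreMatrix,
        pairs: pd.DataFrame,
    ) -> ResponseTable:
        """Predict scaled responses for (drug_id, cell_line_id) pairs.

        Returns a scaled :class:`ResponseTable`; use
        :func:`~gpdrp.response_scaling.unscale_response` for the LN scale.
        """
        if not scores.normalized:
            raise ValueError("pathway scores must be normalized")
        if scores.pathway_ids != self.pathway_ids:
            raise ValueError("pathway axis differs from the model's recorded axis")
        drug_ids = [d for d, _ in drugs]
        unknown_d = sorted(set(pairs["drug_id"]) - set(drug_ids))
        unknown_c = sorted(set(pairs["cell_line_id"]) - set(scores.cell_line_ids))
        if unknown_d or unknown_c:
            raise ValueError(f"unknown ids — drugs: {unknown_d}, cell lines: {unknown_c}")
        graphs = [smiles_to_graph(s, self.schema) for _, s in drugs]
        pe_dim = (
            self.config.encoder.pe_dim
            if self.config.encoder.variant == "GIN_TRANSFORMER"
            else None
        )
        batch = GraphBatch.from_graphs(graphs, pe_dim=pe_dim)
        feats = scores.values.T.copy()
        d_index = {d: i for i, d in enumerate(drug_ids)}
        c_index = {c: i for i, c in enumerate(scores.cell_line_ids)}
        di = pairs["drug_id"].map(d_index).to_numpy(dtype=np.intp)
        ci = pairs["cell_line_id"].map(c_index).to_numpy(dtype=np.intp)
        preds = self._predict_indices(batch, feats, di, ci)
        out = pairs[["drug_id", "cell_line_id"]].copy()
        out["ln_ic50"] = preds
        return ResponseTable(out, scaled=True)

    def evaluate(
        self,
        drugs: list[tuple[str, str]],
        scores: PathwayScoreMatrix,
        responses: ResponseTable,
        scale: str = "scaled",
    ) -> EvalReport:
        """RMSE and Pearson r between observed and predicted responses."""
        lab = (responses if responses.scaled else responses.scale()).labeled
        pred = self.predict_pairs(drugs, scores, lab)
        y, p = lab["ln_ic50"].to_numpy(), pred.records["ln_ic50"].to_numpy()
        if scale == "ln":
            y, p = unscale_response(y), unscale_response(p)
        elif scale != "scaled":
            raise ValueError("scale must be 'scaled' or 'ln'")
        return EvalReport(rmse=rmse(y, p), pccs=pearson(y, p), n_pairs=len(y), scale=scale)

    # -- persistence ---------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(),
            "schema": {
                "symbol_vocabulary": list(self.schema.symbol_vocabulary),
                "max_degree": self.schema.max_degree,
                "max_num_hs": self.schema.max_num_hs,
                "max_implicit_valence": self.schema.max_implicit_valence,
                "fingerprint": self.schema.fingerprint(),
            },
            "pathway_ids": self.pathway_ids,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        np.savez(directory / "weights.npz", **self.state_arrays())

    @classmethod
    def load(cls, directory: str | Path) -> "GPDRP":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        cfg_d = meta["config"]
        cfg = ModelConfig(
            encoder=EncoderConfig(**cfg_d["encoder"]),
            **{k: v for k, v in cfg_d.items() if k != "encoder"},
        )
        cfg.fusion_dims = tuple(cfg.fusion_dims)
        schema = AtomFeatureSchema(
            tuple(meta["schema"]["symbol_vocabulary"]),
            meta["schema"]["max_degree"],
            meta["schema"]["max_num_hs"],
            meta["schema"]["max_implicit_valence"],
        )
        if schema.fingerprint() != meta["schema"]["fingerprint"]:
            raise ValueError("schema fingerprint mismatch in checkpoint")
        model = cls(cfg, schema, meta["pathway_ids"])
        with np.load(directory / "weights.npz") as npz:
            model.load_state_arrays({k: npz[k] for k in npz.files})
        model.eval()
        return model


def pair_universe(n_drugs: int, n_cell_lines: int, n_unlabeled: int = 0) -> dict[str, int]:
    """Bookkeeping for a drug × cell-line screen: total and labeled pair counts."""
    total = n_drugs * n_cell_lines
    if not 0 <= n_unlabeled <= total:
        raise ValueError("unlabeled count out of range")
    return {"total_pairs": total, "unlabeled_pairs": n_unlabeled, "labeled_pairs": total - n_unlabeled}
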