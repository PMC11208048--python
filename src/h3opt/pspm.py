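"""PLM-conditioned coordinate predictor for CDR-H3 loops.

A single weight-shared update block — row-wise gated multi-head attention
with pair bias, an outer-product-mean residue-to-pair update, and outgoing /
incoming triangular multiplicative updates — is applied ``block_iterations``
times to the residue [L, C] and pair [L, L, P] representations projected
from the input features. Language-model embeddings are passed through a
linear layer, concatenated with the residue representation, and driven
through three linear head layers that emit CA coordinates (Angstrom, in the
aligned frame) for the H3-masked positions.

Triangular-update output projections are zero-initialised, so at
initialisation those updates are exact identities; training turns them on.
Weight sharing keeps the parameter count independent of the iteration
count. Training runs Adam with decoupled weight decay under a staged
schedule that freezes either the (mock) language-model side or the main
network, mirroring the freeze-then-finetune recipe used for PLM-backed
predictors.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .featurize import FeatureBundle, N_PAIR_CHANNELS, N_RESIDUE_CHANNELS
from .fixtures import mock_embeddings


@dataclass(frozen=True)
class PspmConfig:
    residue_channels: int = 64
    pair_channels: int = 64
    heads: int = 8
    block_iterations: int = 4
    head_hidden: int = 64
    opm_hidden: int = 16
    dropout: float = 0.25
    embed_dim: int = 32
    seed: int = 0

    def __post_init__(self):
        if min(self.residue_channels, self.pair_channels, self.heads,
               self.block_iterations, self.head_hidden, self.opm_hidden,
               self.embed_dim) < 1:
            raise ValueError("all architecture sizes must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.residue_channels % self.heads:
            raise ValueError("residue_channels must be divisible by heads")


class MockEmbeddingProvider:
    """Deterministic per-residue embedding provider with a trainable stage.

    The fixed part hashes (sequence, position) into unit-variance vectors;
    a trainable square projection stands in for the language model's hidden
    layers so the staged freeze/finetune schedule has real parameters to
    mask. Registered under the ``plm.`` parameter prefix.
    """

    name = "mock"

    def __init__(self, embed_dim: int = 32, seed: int = 0):
        self.embed_dim = embed_dim
        self.seed = seed

    def embed(self, sequence: str) -> np.ndarray:
        return mock_embeddings(sequence, dim=self.embed_dim, seed=self.seed)

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        e = self.embed_dim
        return {
            "plm.proj": np.eye(e) + 0.05 * rng.standard_normal((e, e)),
            "plm.bias": np.zeros(e),
        }


@dataclass
class TrainingState:
    stage: str = ""
    step: int = 0
    adam_m: dict[str, np.ndarray] = field(default_factory=dict)
    adam_v: dict[str, np.ndarray] = field(default_factory=dict)


class PspmModel:
    def __init__(self, config: PspmConfig,
                 provider: MockEmbeddingProvider | None = None):
        self.config = config
        self.provider = provider or MockEmbeddingProvider(
            embed_dim=config.embed_dim, seed=config.seed
        )
        if self.provider.embed_dim != config.embed_dim:
            raise ValueError("provider embed_dim must match config.embed_dim")
        self.params: dict[str, np.ndarray] = self._init_params()
        self.training_state = TrainingState()

    # -- parameters --------------------------------------------------------

    def _init_params(self) -> dict[str, np.ndarray]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        c, p, h = cfg.residue_channels, cfg.pair_channels, cfg.heads
        o = cfg.opm_hidden
        e = cfg.embed_dim
        hh = cfg.head_hidden

        def lin(n_in, n_out):
            return rng.standard_normal((n_in, n_out)) / np.sqrt(n_in)

        params = {
            "proj_res.w": lin(N_RESIDUE_CHANNELS, c),
            "proj_res.b": np.zeros(c),
            "proj_pair.w": lin(N_PAIR_CHANNELS, p),
            "proj_pair.b": np.zeros(p),
            # row-wise gated multi-head attention with pair bias
            "attn.ln.g": np.ones(c), "attn.ln.b": np.zeros(c),
            "attn.wq": lin(c, c), "attn.wk": lin(c, c), "attn.wv": lin(c, c),
            "attn.wbias": lin(p, h),
            "attn.wgate": np.zeros((c, c)), "attn.bgate": np.ones(c),
            "attn.wo": lin(c, c), "attn.bo": np.zeros(c),
            # outer product mean (residue -> pair)
            "opm.ln.g": np.ones(c), "opm.ln.b": np.zeros(c),
            "opm.wa": lin(c, o), "opm.ba": np.zeros(o),
            "opm.wb": lin(c, o), "opm.bb": np.zeros(o),
            "opm.wo": lin(o * o, p) * 0.1, "opm.bo": np.zeros(p),
            # embedding path and heads
            "embed.w": lin(e, c), "embed.b": np.zeros(c),
            "head1.w": lin(2 * c, hh), "head1.b": np.zeros(hh),
            "head2.w": lin(hh, hh), "head2.b": np.zeros(hh),
            "head3.w": lin(hh, 3) * 0.1, "head3.b": np.zeros(3),
        }
        for name in ("tri_out", "tri_in"):
            params.update({
                f"{name}.ln.g": np.ones(p), f"{name}.ln.b": np.zeros(p),
                f"{name}.wa": lin(p, p), f"{name}.ba": np.zeros(p),
                f"{name}.wag": np.zeros((p, p)), f"{name}.bag": np.ones(p),
                f"{name}.wb": lin(p, p), f"{name}.bb": np.zeros(p),
                f"{name}.wbg": np.zeros((p, p)), f"{name}.bbg": np.ones(p),
                f"{name}.lnmid.g": np.ones(p), f"{name}.lnmid.b": np.zeros(p),
                # zero-init output: the update is an identity until trained
                f"{name}.wo": np.zeros((p, p)), f"{name}.bo": np.zeros(p),
                f"{name}.wg": np.zeros((p, p)), f"{name}.bg": np.ones(p),
            })
        params.update(self.provider.init_params(rng))
        return params

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _tensors(self, trainable: set[str] | None = None) -> dict[str, Tensor]:
        return {
            k: Tensor(v, requires_grad=(trainable is None or k in trainable))
            for k, v in self.params.items()
        }

    # -- forward -----------------------------------------------------------

    def _forward_graph(
        self,
        t: dict[str, Tensor],
        feats: FeatureBundle,
        embeddings: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
        aux: dict | None = None,
    ) -> Tensor:
        cfg = self.config
        l = feats.length
        if embeddings.shape[0] != l:
            raise ValueError(
                f"embeddings length {embeddings.shape[0]} != feature length {l}"
            )
        if embeddings.shape[1] != cfg.embed_dim:
            raise ValueError("embedding dim mismatch with config.embed_dim")
        n_h3 = int(feats.h3_mask.sum())
        if n_h3 < 1:
            raise ValueError("h3_mask must mark at least one residue")
        h, dh = cfg.heads, cfg.residue_channels // cfg.heads
        p = cfg.pair_channels

        def dropout(x: Tensor) -> Tensor:
            if not training or cfg.dropout == 0.0:
                return x
            keep = (dropout_rng.random(x.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            return x * keep

        def linear(x, name):
            return x @ t[f"{name}.w"] + t[f"{name}.b"]

        r = linear(Tensor(feats.residue_feats), "proj_res")
        z = linear(Tensor(feats.pair_feats), "proj_pair")

        for _ in range(cfg.block_iterations):
            # row-wise gated multi-head attention with pair bias
            rn = ad.layer_norm(r, t["attn.ln.g"], t["attn.ln.b"])
            q = (rn @ t["attn.wq"]).reshape(l, h, dh)
            k = (rn @ t["attn.wk"]).reshape(l, h, dh)
            v = (rn @ t["attn.wv"]).reshape(l, h, dh)
            scores = ad.einsum("ihd,jhd->hij", q, k) * (1.0 / np.sqrt(dh))
            bias = (z @ t["attn.wbias"]).transpose(2, 0, 1)  # [H, L, L]
            weights = (scores + bias).softmax(axis=-1)
            if aux is not None:
                aux.setdefault("attention_weights", []).append(weights.data.copy())
            ctx = ad.einsum("hij,jhd->ihd", weights, v).reshape(l, h * dh)
            gate = (rn @ t["attn.wgate"] + t["attn.bgate"]).sigmoid()
            r = r + dropout((gate * ctx) @ t["attn.wo"] + t["attn.bo"])

            # outer product mean: residue representation feeds the pair
            on = ad.layer_norm(r, t["opm.ln.g"], t["opm.ln.b"])
            oa = on @ t["opm.wa"] + t["opm.ba"]
            ob = on @ t["opm.wb"] + t["opm.bb"]
            outer = ad.einsum("ia,jb->ijab", oa, ob).reshape(
                l, l, cfg.opm_hidden * cfg.opm_hidden
            )
            z = z + outer @ t["opm.wo"] + t["opm.bo"]

            # triangular multiplicative updates, outgoing then incoming
            for name, contraction in (("tri_out", "ikc,jkc->ijc"),
                                      ("tri_in", "kic,kjc->ijc")):
                zn = ad.layer_norm(z, t[f"{name}.ln.g"], t[f"{name}.ln.b"])
                a = (zn @ t[f"{name}.wag"] + t[f"{name}.bag"]).sigmoid() * (
                    zn @ t[f"{name}.wa"] + t[f"{name}.ba"]
                )
                b = (zn @ t[f"{name}.wbg"] + t[f"{name}.bbg"]).sigmoid() * (
                    zn @ t[f"{name}.wb"] + t[f"{name}.bb"]
                )
                s = ad.layer_norm(
                    ad.einsum(contraction, a, b),
                    t[f"{name}.lnmid.g"], t[f"{name}.lnmid.b"],
                )
                gate = (zn @ t[f"{name}.wg"] + t[f"{name}.bg"]).sigmoid()
                z = z + gate * (s @ t[f"{name}.wo"] + t[f"{name}.bo"])

        e = Tensor(embeddings)
        e = e @ t["plm.proj"] + t["plm.bias"]
        e = e @ t["embed.w"] + t["embed.b"]
        x = ad.concatenate([r, e], axis=-1)
        x = dropout((x @ t["head1.w"] + t["head1.b"]).relu())
        x = dropout((x @ t["head2.w"] + t["head2.b"]).relu())
        coords = x @ t["head3.w"] + t["head3.b"]  # [L, 3]
        h3_idx = np.flatnonzero(feats.h3_mask > 0)
        return coords[h3_idx]

    def forward(
        self,
        feats: FeatureBundle,
        embeddings: np.ndarray | None = None,
        return_aux: bool = False,
    ) -> np.ndarray | tuple[np.ndarray, dict]:
        """Predict H3 CA coordinates [n_h3, 3] in evaluation mode."""
        if embeddings is None:
            embeddings = self.provider.embed(feats.sequence)
        aux: dict = {}
        t = self._tensors(trainable=set())
        out = self._forward_graph(t, feats, embeddings, training=False,
                                  aux=aux if return_aux else None)
        return (out.data, aux) if return_aux else out.data

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: JSON header + named parameter arrays."""
        header = json.dumps(
            {
                "config": asdict(self.config),
                "stage": self.training_state.stage,
                "step": self.training_state.step,
            }
        )
        arrays = {k.replace(".", "__"): v for k, v in self.params.items()}
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @staticmethod
    def load(path) -> "PspmModel":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            model = PspmModel(PspmConfig(**header["config"]))
            for k in data.files:
                if k == "__header__":
                    continue
                model.params[k.replace("__", ".")] = data[k]
            model.training_state.stage = header["stage"]
            model.training_state.step = header["step"]
        return model


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over all 3n coordinate components of the squared error (A^2)."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


STAGES = ("freeze_plm", "freeze_main", "joint")


def trainable_names(model: PspmModel, stage: str) -> set[str]:
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    all_names = set(model.params)
    plm = {n for n in all_names if n.startswith("plm.")}
    if stage == "freeze_plm":
        return all_names - plm
    if stage == "freeze_main":
        return plm
    return all_names


def gradients(
    model: PspmModel,
    dataset: list[tuple[FeatureBundle, np.ndarray, np.ndarray]],
    stage: str = "joint",
    training: bool = True,
    dropout_seed: int = 0,
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and per-parameter gradients of the mean MSE over ``dataset``.

    Each dataset item is (features, embeddings, target H3 CA coords).
    Frozen-stage parameters receive an exactly-zero gradient.
    """
    trainable = trainable_names(model, stage)
    t = model._tensors(trainable=trainable)
    rng = np.random.default_rng(dropout_seed)
    losses = []
    for feats, emb, target in dataset:
        pred = model._forward_graph(t, feats, emb, training=training, dropout_rng=rng)
        diff = pred - Tensor(np.asarray(target, dtype=float))
        losses.append((diff * diff).mean())
    total = ad.stack(losses).mean()
    total.backward()
    grads = {
        k: (t[k].grad if t[k].grad is not None else np.zeros_like(model.params[k]))
        for k in model.params
    }
    return float(total.data), grads


@dataclass
class StageSchedule:
    stage: str
    steps: int
    lr: float = 1e-4


def train_pspm(
    model: PspmModel,
    dataset: list[tuple[FeatureBundle, np.ndarray, np.ndarray]],
    schedule: list[StageSchedule],
    weight_decay: float = 5e-4,
    betas: tuple[float, float] = (0.9, 0.999),
    eps: float = 1e-8,
    seed: int = 0,
) -> list[float]:
    """Staged Adam training (decoupled weight decay); returns the loss history.

    All randomness (dropout masks) derives from ``seed``. An ``lr`` of zero
    leaves parameters bitwise unchanged.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    state = model.training_state
    history: list[float] = []
    b1, b2 = betas
    for sched in schedule:
        trainable = trainable_names(model, sched.stage)
        state.stage = sched.stage
        for _ in range(sched.steps):
            loss, grads = gradients(
                model, dataset, stage=sched.stage,
                dropout_seed=seed + state.step,
            )
            history.append(loss)
            state.step += 1
            if sched.lr == 0.0:
                continue
            for name in sorted(trainable):
                g = grads[name]
                m = state.adam_m.setdefault(name, np.zeros_like(g))
                v = state.adam_v.setdefault(name, np.zeros_like(g))
                m[:] = b1 * m + (1 - b1) * g
                v[:] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1 ** state.step)
                vhat = v / (1 - b2 ** state.step)
                model.params[name] = model.params[name] - sched.lr * (
                    mhat / (np.sqrt(vhat) + eps)
                    + weight_decay * model.params[name]
                )
    return history
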