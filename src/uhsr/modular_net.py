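"""Modular neural networks that distill scalar retention indices.

A modular network partitions the 23 input features into named, disjoint
groups; each group is processed by its own sub-model (an MLP with no
parameter sharing across groups) that emits one scalar latent, and a head
MLP maps the latent vector to the predicted Rf through a logistic output.
By construction each latent's receptive field is restricted to its group.

Three hierarchical stages share this architecture and all predict Rf:

    stage 1: {solvent(5), solute(18)}                     -> (Psi, xi)
    stage 2: {solvent(5), FGdist(2), FG(16)}              -> (alpha, beta)
    stage 3: {solvent(5), FGdist(2), FG1..FG5(2,3,2,5,4)} -> (gamma1..gamma5)

Latents are reported in a fixed gauge: standardized to mean 0 / variance 1
on the training split, with signs canonicalized against documented
references (e.g. corr(xi, Rf) >= 0, corr(Psi, MeOH) >= 0).

Everything here is plain numpy with hand-written backpropagation and Adam,
which keeps seeded training bit-reproducible run to run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from threadpoolctl import threadpool_limits

from .errors import ConfigError, SchemaError, TrainingError, ValidationError
from .features import FEATURE_NAMES, TLCRecord, features_matrix, rf_vector
from .util import sigmoid

__all__ = [
    "HyperParams", "FeatureGrouping", "TrainedStage", "ModularNet",
    "build_network", "train", "extract_latents", "probe",
    "canonicalize_sign", "run_hierarchy", "HierarchyConfig",
    "HierarchyResult", "stage1_grouping", "stage2_grouping",
    "stage3_grouping", "STAGE3_FG_SUBGROUPS", "save_stage", "load_stage",
    "LATENT_COLUMNS",
]

#: FG subgroup membership for stage 3, one tuple per fine-grained index.
STAGE3_FG_SUBGROUPS = (
    ("CtAm", "CtCO2H"),
    ("CtPh", "CtNH2", "CtOH"),
    ("CtNO2", "CtRCO2R"),
    ("CtF", "CtROR", "CtR2CO", "CtAl", "CtCN"),
    ("CtMe", "CtCl", "CtBr", "CtI"),
)

LATENT_COLUMNS = ("psi", "xi", "alpha", "beta",
                  "gamma1", "gamma2", "gamma3", "gamma4", "gamma5")

_LEAKY_SLOPE = 0.01


@dataclass(frozen=True)
class HyperParams:
    """Training hyperparameters; defaults follow the reference protocol
    (two hidden layers of 50 LeakyReLU units per sub-model, Adam with
    learning rate 0.01, batch size 2048, 1000 epochs, best-validation
    checkpoint selection)."""

    hidden_width: int = 50
    hidden_depth: int = 2
    #: hidden layers in the head that combines the latents; 0 gives the
    #: minimal head sigma(w . z + b), which pins the latents to an affine
    #: gauge of whatever the head consumes
    head_depth: int = 2
    batch_size: int = 2048
    learning_rate: float = 0.01
    epochs: int = 1000
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.hidden_width, self.hidden_depth, self.batch_size,
               self.epochs) <= 0 or self.head_depth < 0:
            raise ConfigError("hyperparameters must be positive")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ConfigError("validation_fraction must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")


@dataclass(frozen=True)
class FeatureGrouping:
    """Named, disjoint partition of the feature positions, one latent per
    group."""

    groups: tuple  # of (name, tuple of feature indices)
    latents: tuple  # latent name per group
    n_features: int = 23

    def __post_init__(self):
        seen: set[int] = set()
        for name, idx in self.groups:
            s = set(idx)
            if len(s) != len(idx):
                raise ConfigError(f"group {name!r} repeats an index")
            if s & seen:
                raise ConfigError(f"group {name!r} overlaps another group")
            seen |= s
        if seen != set(range(self.n_features)):
            missing = sorted(set(range(self.n_features)) - seen)
            raise ConfigError(
                f"grouping does not cover features {missing}: incomplete cover")
        if len(self.latents) != len(self.groups):
            raise ConfigError("one latent name per group required")

    @property
    def names(self) -> tuple:
        return tuple(name for name, _ in self.groups)

    def indices(self, name: str) -> tuple:
        for gname, idx in self.groups:
            if gname == name:
                return tuple(idx)
        raise ConfigError(f"unknown group {name!r}")


def _idx(names: Sequence[str]) -> tuple:
    return tuple(FEATURE_NAMES.index(n) for n in names)


_SOLVENT_IDX = tuple(range(5))
_FG_IDX = tuple(range(5, 21))
_FGDIST_IDX = (21, 22)  # NBen, DM


def stage1_grouping() -> FeatureGrouping:
    return FeatureGrouping(
        groups=(("solvent", _SOLVENT_IDX), ("solute", _FG_IDX + _FGDIST_IDX)),
        latents=("psi", "xi"),
    )


def stage2_grouping() -> FeatureGrouping:
    return FeatureGrouping(
        groups=(("solvent", _SOLVENT_IDX), ("FGdist", _FGDIST_IDX),
                ("FG", _FG_IDX)),
        latents=("psi_s2", "alpha", "beta"),
    )


def stage3_grouping() -> FeatureGrouping:
    groups = [("solvent", _SOLVENT_IDX), ("FGdist", _FGDIST_IDX)]
    latents = ["psi_s3", "alpha_s3"]
    for j, members in enumerate(STAGE3_FG_SUBGROUPS):
        groups.append((f"FG{j + 1}", _idx(members)))
        latents.append(f"gamma{j + 1}")
    return FeatureGrouping(groups=tuple(groups), latents=tuple(latents))


# ---------------------------------------------------------------------------
# Plain-numpy MLP with backprop
# ---------------------------------------------------------------------------

class _MLP:
    def __init__(self, sizes, rng, slope=_LEAKY_SLOPE):
        self.slope = slope
        self.W = [rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
                  for fan_in, fan_out in zip(sizes[:-1], sizes[1:])]
        self.b = [np.zeros(fan_out) for fan_out in sizes[1:]]

    def forward(self, X, need_cache=False):
        caches = []
        h = X
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if need_cache:
                caches.append((h, z))
            h = z if i == last else np.where(z > 0, z, self.slope * z)
        return (h, caches) if need_cache else h

    def backward(self, caches, G):
        """Gradient of the loss wrt parameters and input, given dL/d(output)."""
        grads = [None] * len(self.W)
        for i in range(len(self.W) - 1, -1, -1):
            x, _ = caches[i]
            grads[i] = (x.T @ G, G.sum(axis=0))
            G = G @ self.W[i].T
            if i > 0:
                z_prev = caches[i - 1][1]
                G = G * np.where(z_prev > 0, 1.0, self.slope)
        return grads, G

    def parameters(self):
        for i in range(len(self.W)):
            yield self.W[i]
            yield self.b[i]

    def snapshot(self):
        return [W.copy() for W in self.W], [b.copy() for b in self.b]

    def restore(self, snap):
        self.W = [W.copy() for W in snap[0]]
        self.b = [b.copy() for b in snap[1]]


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v, g in zip(self.params, self.m, self.v, grads):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ModularNet:
    """One sub-MLP per feature group emitting a scalar latent, plus a head
    MLP with logistic output combining the latents into Rf."""

    def __init__(self, grouping: FeatureGrouping, hp: HyperParams,
                 rng: np.random.Generator):
        self.grouping = grouping
        self.hp = hp
        hidden = [hp.hidden_width] * hp.hidden_depth
        self.subs = [_MLP([len(idx)] + hidden + [1], rng)
                     for _, idx in grouping.groups]
        head_hidden = [hp.hidden_width] * hp.head_depth
        self.head = _MLP([len(grouping.groups)] + head_hidden + [1], rng)

    @property
    def k(self) -> int:
        return len(self.subs)

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.grouping.n_features:
            raise SchemaError(
                f"expected {self.grouping.n_features} features, got {X.shape[1]}")
        return X

    def latents_raw(self, X) -> np.ndarray:
        X = self._check(X)
        cols = [sub.forward(X[:, list(idx)])
                for sub, (_, idx) in zip(self.subs, self.grouping.groups)]
        return np.concatenate(cols, axis=1)

    def forward(self, X) -> np.ndarray:
        z = self.latents_raw(X)
        return sigmoid(self.head.forward(z)[:, 0])

    def _train_step(self, X, t, optimizers):
        caches_sub = []
        zs = []
        for sub, (_, idx) in zip(self.subs, self.grouping.groups):
            z, cache = sub.forward(X[:, list(idx)], need_cache=True)
            zs.append(z)
            caches_sub.append(cache)
        Z = np.concatenate(zs, axis=1)
        o, cache_head = self.head.forward(Z, need_cache=True)
        y = sigmoid(o[:, 0])
        resid = y - t
        loss = float(np.mean(resid * resid))
        B = X.shape[0]
        G_o = (2.0 / B) * resid * y * (1.0 - y)
        g_head, G_Z = self.head.backward(cache_head, G_o[:, None])
        grads = []
        for i, (sub, cache) in enumerate(zip(self.subs, caches_sub)):
            g_sub, _ = sub.backward(cache, G_Z[:, i:i + 1])
            grads.append(g_sub)
        flat = []
        for g_sub in grads:
            for gW, gb in g_sub:
                flat.extend([gW, gb])
        for gW, gb in g_head:
            flat.extend([gW, gb])
        optimizers.step(flat)
        return loss

    def parameters(self):
        for sub in self.subs:
            yield from sub.parameters()
        yield from self.head.parameters()

    def snapshot(self):
        return [s.snapshot() for s in self.subs] + [self.head.snapshot()]

    def restore(self, snaps):
        for sub, snap in zip(self.subs, snaps[:-1]):
            sub.restore(snap)
        self.head.restore(snaps[-1])


def build_network(grouping: FeatureGrouping, hp: Optional[HyperParams] = None
                  ) -> ModularNet:
    """Instantiate an untrained modular network (seeded initialization)."""
    hp = hp or HyperParams()
    rng = np.random.default_rng(hp.seed)
    return ModularNet(grouping, hp, rng)


# ---------------------------------------------------------------------------
# Training and the trained-stage container
# ---------------------------------------------------------------------------

@dataclass
class TrainedStage:
    """A trained modular network plus the latent gauge (standardization and
    sign) fixed on its training split."""

    network: ModularNet
    grouping: FeatureGrouping
    hp: HyperParams
    shift: np.ndarray
    scale: np.ndarray
    sign: np.ndarray
    train_loss_trace: list
    val_loss_trace: list
    best_epoch: int
    flips: tuple = ()

    @property
    def latent_names(self) -> tuple:
        return self.grouping.latents

    def predict(self, X) -> np.ndarray:
        """Predicted Rf, in (0, 1) for any finite input."""
        return self.network.forward(_as_matrix(X))

    def latents(self, X) -> np.ndarray:
        """Standardized latents: sign * (raw - shift) / scale."""
        raw = self.network.latents_raw(_as_matrix(X))
        return self.sign * (raw - self.shift) / self.scale


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        return X
    if len(X) > 0 and isinstance(X[0], TLCRecord):
        return features_matrix(X)
    return np.asarray(X, dtype=float)


def train(network: ModularNet, records_or_X, y=None,
          hp: Optional[HyperParams] = None) -> TrainedStage:
    """Train a modular network on Rf with MSE loss and Adam.

    A seeded validation split (hp.validation_fraction) is held out for
    best-checkpoint selection only.  Fully reproducible under a fixed seed:
    BLAS is pinned to one thread for the duration of training, since
    multi-threaded reductions are not bitwise deterministic.
    """
    with threadpool_limits(limits=1):
        return _train_single_threaded(network, records_or_X, y, hp)


def _train_single_threaded(network, records_or_X, y, hp):
    hp = hp or network.hp
    if y is None:
        X = features_matrix(records_or_X)
        y = rf_vector(records_or_X)
    else:
        X = np.asarray(records_or_X, dtype=float)
        y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        raise TrainingError("empty training data")
    if X.shape[0] != n:
        raise SchemaError("X and y length mismatch")

    rng = np.random.default_rng(np.random.SeedSequence([hp.seed, 1]))
    perm = rng.permutation(n)
    n_val = max(1, int(round(n * hp.validation_fraction)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    n_train = len(train_idx)
    if math.ceil(n_train / hp.batch_size) < 2:
        raise TrainingError(
            f"need at least 2 batches after the validation split "
            f"(n_train={n_train}, batch_size={hp.batch_size})")

    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = _Adam(network.parameters(), lr=hp.learning_rate)
    best = (math.inf, None, -1)
    train_trace, val_trace = [], []
    for epoch in range(hp.epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, hp.batch_size):
            batch = order[start:start + hp.batch_size]
            loss = network._train_step(Xtr[batch], ytr[batch], opt)
            if not math.isfinite(loss):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss * len(batch)
        train_trace.append(epoch_loss / n_train)
        resid = network.forward(Xval) - yval
        val_loss = float(np.mean(resid * resid))
        if not math.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        val_trace.append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, network.snapshot(), epoch)

    network.restore(best[1])
    raw = network.latents_raw(Xtr)
    shift = raw.mean(axis=0)
    scale = raw.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return TrainedStage(
        network=network, grouping=network.grouping, hp=hp,
        shift=shift, scale=scale, sign=np.ones(network.k),
        train_loss_trace=train_trace, val_loss_trace=val_trace,
        best_epoch=best[2],
    )


def extract_latents(stage: TrainedStage, records_or_X,
                    ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-sample standardized latents as a DataFrame (one column per
    latent, optional id column first)."""
    X = _as_matrix(records_or_X)
    if ids is None and len(records_or_X) and isinstance(records_or_X[0], TLCRecord):
        ids = [r.id for r in records_or_X]
    Z = stage.latents(X)
    df = pd.DataFrame(Z, columns=list(stage.latent_names))
    if ids is not None:
        df.insert(0, "id", list(ids))
    return df


def probe(stage: TrainedStage, group: str, which) -> float:
    """Evaluate a group's latent on a basis input, on the standardized scale.

    `which` may be a feature name inside the group, an intra-group index, or
    a vector of the group's dimension (e.g. a one-hot FG vector or a pure
    solvent composition).
    """
    idx = stage.grouping.indices(group)
    gi = stage.grouping.names.index(group)
    d = len(idx)
    if isinstance(which, str):
        feat_names = [FEATURE_NAMES[i] for i in idx]
        if which not in feat_names:
            raise ConfigError(f"feature {which!r} not in group {group!r}")
        v = np.zeros(d)
        v[feat_names.index(which)] = 1.0
    elif isinstance(which, (int, np.integer)):
        if not 0 <= which < d:
            raise ConfigError(
                f"index {which} outside group {group!r} of size {d}")
        v = np.zeros(d)
        v[which] = 1.0
    else:
        v = np.asarray(which, dtype=float)
        if v.shape != (d,):
            raise SchemaError(
                f"basis vector must have shape ({d},), got {v.shape}")
    raw = float(stage.network.subs[gi].forward(v[None, :])[0, 0])
    return float(stage.sign[gi] * (raw - stage.shift[gi]) / stage.scale[gi])


#: Default sign-canonicalization rules per latent name.  Each entry is
#: (reference, desired sign): the latent is flipped so that its correlation
#: with the reference (a feature name, or "rf" for the target) has the
#: desired sign.  Polarity conventions: higher Psi = stronger eluent
#: (tracks MeOH); higher xi = higher Rf (lower solute polarity); higher
#: beta/gamma = more polar functional groups, hence lower Rf; higher alpha
#: tracks its positive coefficient in the xi equation.
DEFAULT_SIGN_RULES = {
    "psi": ("MeOH", +1), "psi_s2": ("MeOH", +1), "psi_s3": ("MeOH", +1),
    "xi": ("rf", +1),
    "alpha": ("rf", +1), "alpha_s3": ("rf", +1),
    "beta": ("rf", -1),
    "gamma1": ("rf", -1), "gamma2": ("rf", -1), "gamma3": ("rf", -1),
    "gamma4": ("rf", -1), "gamma5": ("rf", -1),
}


def canonicalize_sign(stage: TrainedStage, records_or_X, y=None,
                      rules: Optional[Mapping] = None) -> TrainedStage:
    """Flip latent signs so the documented reference correlations are
    non-negative (after flipping).  Idempotent; flips are recorded."""
    X = _as_matrix(records_or_X)
    if y is None and len(records_or_X) and isinstance(records_or_X[0], TLCRecord):
        y = rf_vector(records_or_X)
    rules = DEFAULT_SIGN_RULES if rules is None else rules
    Z = stage.latents(X)
    sign = stage.sign.copy()
    flips = []
    for i, name in enumerate(stage.latent_names):
        if name not in rules:
            continue
        ref, desired = rules[name]
        if ref == "rf":
            if y is None:
                raise ValidationError("target values required for rf-referenced "
                                      "sign canonicalization")
            r = np.asarray(y, dtype=float)
        else:
            r = X[:, FEATURE_NAMES.index(ref)]
        z = Z[:, i]
        if z.std() == 0.0:
            raise ValidationError(f"zero-variance latent {name!r}")
        if r.std() == 0.0:
            raise ValidationError(f"zero-variance reference {ref!r}")
        corr = float(np.corrcoef(z, r)[0, 1])
        if corr * desired < 0:
            sign[i] = -sign[i]
            flips.append(name)
    return replace(stage, sign=sign, flips=stage.flips + tuple(flips))


# ---------------------------------------------------------------------------
# The three-stage hierarchy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HierarchyConfig:
    hp: HyperParams = field(default_factory=HyperParams)
    seed: int = 0
    canonicalize: bool = True


@dataclass
class HierarchyResult:
    stages: dict           # {"stage1": TrainedStage, ...}
    latent_table: pd.DataFrame  # id, psi, xi, alpha, beta, gamma1..gamma5


def run_hierarchy(records, config: Optional[HierarchyConfig] = None
                  ) -> HierarchyResult:
    """Train the three stages and assemble the unified latent table."""
    config = config or HierarchyConfig()
    X = _as_matrix(records)
    if len(records) and isinstance(records[0], TLCRecord):
        y = rf_vector(records)
        ids = [r.id for r in records]
    else:
        raise SchemaError("run_hierarchy expects a sequence of TLCRecord")

    stages = {}
    groupings = {"stage1": stage1_grouping(), "stage2": stage2_grouping(),
                 "stage3": stage3_grouping()}
    for si, (key, grouping) in enumerate(groupings.items()):
        hp = replace(config.hp, seed=config.seed + si)
        if key == "stage1":
            # the top stage's head is the minimal sigma(w.z + b): the printed
            # governing equation is sigmoid-affine in (Psi, xi), and the
            # minimal head keeps the two latents in an affine gauge of the
            # indices instead of letting the head absorb their nonlinearity
            hp = replace(hp, head_depth=0)
        net = build_network(grouping, hp)
        stage = train(net, X, y, hp)
        if config.canonicalize:
            stage = canonicalize_sign(stage, X, y)
        stages[key] = stage

    table = pd.DataFrame({"id": ids})
    z1 = stages["stage1"].latents(X)
    table["psi"] = z1[:, 0]
    table["xi"] = z1[:, 1]
    z2 = stages["stage2"].latents(X)
    names2 = stages["stage2"].latent_names
    table["alpha"] = z2[:, names2.index("alpha")]
    table["beta"] = z2[:, names2.index("beta")]
    z3 = stages["stage3"].latents(X)
    names3 = stages["stage3"].latent_names
    for j in range(1, 6):
        table[f"gamma{j}"] = z3[:, names3.index(f"gamma{j}")]
    return HierarchyResult(stages=stages, latent_table=table)


# ---------------------------------------------------------------------------
# Serialization: binary parameter file + JSON sidecar
# ---------------------------------------------------------------------------

def save_stage(stage: TrainedStage, prefix: str) -> None:
    """Write `{prefix}.npz` (parameters) and `{prefix}.json` (grouping,
    hyperparameters, standardization, sign, best epoch)."""
    arrays = {}
    for si, sub in enumerate(stage.network.subs):
        for li, (W, b) in enumerate(zip(sub.W, sub.b)):
            arrays[f"sub{si}_W{li}"] = W
            arrays[f"sub{si}_b{li}"] = b
    for li, (W, b) in enumerate(zip(stage.network.head.W, stage.network.head.b)):
        arrays[f"head_W{li}"] = W
        arrays[f"head_b{li}"] = b
    np.savez(prefix + ".npz", **arrays)
    sidecar = {
        "groups": [[name, list(idx)] for name, idx in stage.grouping.groups],
        "latents": list(stage.grouping.latents),
        "hp": {f: getattr(stage.hp, f) for f in
               ("hidden_width", "hidden_depth", "head_depth", "batch_size",
                "learning_rate", "epochs", "validation_fraction", "seed")},
        "shift": stage.shift.tolist(),
        "scale": stage.scale.tolist(),
        "sign": stage.sign.tolist(),
        "best_epoch": stage.best_epoch,
        "flips": list(stage.flips),
    }
    with open(prefix + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_stage(prefix: str) -> TrainedStage:
    with open(prefix + ".json") as fh:
        sidecar = json.load(fh)
    grouping = FeatureGrouping(
        groups=tuple((name, tuple(idx)) for name, idx in sidecar["groups"]),
        latents=tuple(sidecar["latents"]),
    )
    hp = HyperParams(**sidecar["hp"])
    net = build_network(grouping, hp)
    data = np.load(prefix + ".npz")
    for si, sub in enumerate(net.subs):
        sub.W = [data[f"sub{si}_W{li}"] for li in range(len(sub.W))]
        sub.b = [data[f"sub{si}_b{li}"] for li in range(len(sub.b))]
    net.head.W = [data[f"head_W{li}"] for li in range(len(net.head.W))]
    net.head.b = [data[f"head_b{li}"] for li in range(len(net.head.b))]
    return TrainedStage(
        network=net, grouping=grouping, hp=hp,
        shift=np.array(sidecar["shift"]), scale=np.array(sidecar["scale"]),
        sign=np.array(sidecar["sign"]),
        train_loss_trace=[], val_loss_trace=[],
        best_epoch=sidecar["best_epoch"], flips=tuple(sidecar["flips"]),
    )
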