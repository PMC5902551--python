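"""Hierarchical bagged ensemble of feed-forward networks for SNV classification.

The classifier assigns each candidate SNV to one of three classes —
RNA-editing site, genomic SNP, or other artifact — from nothing but the
one-hot encoded sequence window around it.  It is built bottom-up in four
levels, every level combining its children by simple probability averaging:

1. *individual net*: a softmax multilayer perceptron on one flattened
   one-hot window (default hidden sizes 1000 and 100, three outputs);
2. *ensemble*: 20 individual nets, each trained on an independent
   class-balanced bootstrap of the training set (bagging, which also
   neutralises class imbalance);
3. *single-cell module*: one ensemble per input scale (default 101-bp and
   41-bp windows, i.e. flanks 50 and 20, centre-cropped from a common
   wide window), averaged;
4. *component*: one module per gold-standard set (default 11), averaged —
   and the final classifier averages a "separate" and a "pooled"
   component, named for the two labelling procedures that produced their
   gold sets.

All randomness flows from one master seed through a documented derivation
(:func:`derive_seed`): master → level code → module index → member index.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .sequence_windows import CandidateSNV, SequenceWindow, classify_mismatch

logger = logging.getLogger("editnet")

SIMPLEX_TOL = 1e-9

# level codes used in seed derivation
_LEVEL_MEMBER = 1
_LEVEL_MODULE = 2
_LEVEL_COMPONENT = 3


class ClassLabel(IntEnum):
    """The three candidate classes, in the fixed output-column order."""

    EDITING = 0
    SNP = 1
    OTHER = 2


class ScoreTriple(NamedTuple):
    """Class probabilities for one candidate (sums to 1)."""

    p_editing: float
    p_snp: float
    p_other: float


def derive_seed(master: int, *path: int) -> int:
    """Derive a child seed from the master seed and a hierarchy path.

    The path is (level code, module index, member index, ...); distinct
    paths give independent streams.  Result is < 2**31.
    """
    ss = np.random.SeedSequence([int(master), *map(int, path)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Specs and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndividualNetSpec:
    """Architecture of one softmax MLP member."""

    input_flank: int = 50
    hidden_sizes: tuple[int, ...] = (1000, 100)
    n_outputs: int = 3
    activation: str = "relu"
    seed: int = 0

    @property
    def input_dim(self) -> int:
        return (2 * self.input_flank + 1) * 4


@dataclass(frozen=True)
class EnsembleSpec:
    n_members: int = 20
    member_spec: IndividualNetSpec = field(default_factory=IndividualNetSpec)
    #: examples drawn per class per member; "min-class" = size of smallest class
    resample_per_class: int | str = "min-class"

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


@dataclass(frozen=True)
class SingleCellModuleSpec:
    """Per-scale ensembles of one module; scales are window flanks."""

    scales: tuple[int, ...] = (50, 20)
    n_members: int = 20
    hidden_sizes: tuple[int, ...] = (1000, 100)
    activation: str = "relu"
    resample_per_class: int | str = "min-class"

    def __post_init__(self) -> None:
        if not self.scales:
            raise ValueError("at least one scale is required")
        if len(set(self.scales)) != len(self.scales):
            raise ValueError("scales must be distinct")


@dataclass(frozen=True)
class TrainingConfig:
    k_folds: int = 5
    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


# ---------------------------------------------------------------------------
# Window tensors
# ---------------------------------------------------------------------------

def stack_windows(windows: Sequence[SequenceWindow]) -> np.ndarray:
    """Stack windows of equal flank into an (n, 2f+1, 4) one-hot tensor."""
    if not windows:
        raise ValueError("no windows given")
    flanks = {w.flank for w in windows}
    if len(flanks) != 1:
        raise ValueError(f"windows have mixed flanks {sorted(flanks)}")
    return np.stack([w.onehot for w in windows]).astype(np.float32)


def crop_centre(X: np.ndarray, flank: int) -> np.ndarray:
    """Centre-anchored crop of an (n, W, 4) tensor to width 2·flank+1.

    All scales share the candidate base at their midpoint.
    """
    X = np.asarray(X)
    width = X.shape[1]
    if width % 2 != 1:
        raise ValueError(f"window width {width} is not odd")
    have = (width - 1) // 2
    if flank > have:
        raise ValueError(f"window flank {have} narrower than requested scale {flank}")
    mid = have
    return X[:, mid - flank : mid + flank + 1, :]


# ---------------------------------------------------------------------------
# Sampling and folds
# ---------------------------------------------------------------------------

def balanced_bootstrap(y: np.ndarray, n_per_class: int, seed: int) -> np.ndarray:
    """Indices of a class-balanced bootstrap: ``n_per_class`` draws with
    replacement from each of the three classes, independently per class.

    Bagging over such draws both decorrelates ensemble members and removes
    class imbalance from each member's training set.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    parts = []
    for label in ClassLabel:
        idx = np.flatnonzero(y == label)
        if idx.size == 0:
            raise ValueError(f"class {label.name} absent from training data")
        parts.append(rng.choice(idx, size=n_per_class, replace=True))
    return np.concatenate(parts)


def kfold_split(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partitions (train, test) of indices.

    Balancing (bootstrap resampling) is applied inside training folds only,
    by the training routines — never to test folds.
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if y.size < k:
        raise ValueError(f"dataset size {y.size} smaller than k={k}")
    counts = np.bincount(y, minlength=3)
    if (counts[counts > 0] < k).any():
        logger.warning("a class has fewer than k=%d examples; stratification degenerates", k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros_like(y), y)]


# ---------------------------------------------------------------------------
# Model levels
# ---------------------------------------------------------------------------

class IndividualNet:
    """One trained softmax MLP: flattened one-hot window → class probabilities.

    Weights live in plain numpy arrays; the forward pass (ReLU hiddens,
    softmax output) is self-contained so serialized models reload and
    score bit-exactly.
    """

    def __init__(self, spec: IndividualNetSpec, weights: list[np.ndarray], biases: list[np.ndarray]):
        self.spec = spec
        self.weights = weights
        self.biases = biases

    @property
    def input_flank(self) -> int:
        return self.spec.input_flank

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Score an (n, W, 4) one-hot tensor (W at least the net's scale)."""
        Xc = crop_centre(X, self.spec.input_flank)
        a = Xc.reshape(Xc.shape[0], -1).astype(np.float64)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        z = a @ self.weights[-1] + self.biases[-1]
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def train_individual_net(
    X: np.ndarray, y: np.ndarray, spec: IndividualNetSpec, config: TrainingConfig
) -> IndividualNet:
    """Fit one MLP member; deterministic given ``spec.seed``.

    ``X`` is an (n, W, 4) one-hot tensor at the spec's flank (wider windows
    are centre-cropped).  All three classes must appear in ``y``.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if spec.activation != "relu":
        raise ValueError("only relu hidden activation is supported")
    Xc = crop_centre(X, spec.input_flank)
    flat = Xc.reshape(Xc.shape[0], -1)
    present = np.unique(y)
    if len(present) < 3:
        missing = [l.name for l in ClassLabel if l not in present]
        raise ValueError(f"classes missing from training data: {missing}")
    clf = MLPClassifier(
        hidden_layer_sizes=spec.hidden_sizes,
        activation="relu",
        solver=config.optimizer_name,
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, flat.shape[0]),
        max_iter=config.epochs,
        random_state=spec.seed,
        alpha=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(flat, y)
    # classes_ is sorted 0,1,2 == ClassLabel order
    return IndividualNet(spec, [w.copy() for w in clf.coefs_], [b.copy() for b in clf.intercepts_])


def average_probabilities(triples: Iterable[Sequence[float]]) -> ScoreTriple:
    """Componentwise arithmetic mean of probability triples."""
    arr = np.asarray(list(triples), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot average an empty list of probability triples")
    mean = arr.mean(axis=0)
    return ScoreTriple(*map(float, mean))


class _Averaging:
    """Shared predict logic: mean of children's probability matrices."""

    children: list

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.mean([c.predict_proba(X) for c in self.children], axis=0)


class EnsembleNet(_Averaging):
    """A bagged committee of individual nets at one input scale."""

    def __init__(self, members: list[IndividualNet]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.children = self.members = members

    @property
    def input_flank(self) -> int:
        return max(m.input_flank for m in self.members)


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    spec: EnsembleSpec,
    config: TrainingConfig,
    seed: int = 0,
) -> EnsembleNet:
    """Train ``n_members`` nets, each on its own balanced bootstrap draw."""
    y = np.asarray(y)
    if spec.resample_per_class == "min-class":
        counts = np.bincount(y, minlength=3)
        if (counts == 0).any():
            missing = [ClassLabel(i).name for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"classes missing from training data: {missing}")
        n_per_class = int(counts.min())
    else:
        n_per_class = int(spec.resample_per_class)
    members = []
    for m in range(spec.n_members):
        member_seed = derive_seed(seed, _LEVEL_MEMBER, spec.member_spec.input_flank, m)
        idx = balanced_bootstrap(y, n_per_class, member_seed)
        member_spec = IndividualNetSpec(
            input_flank=spec.member_spec.input_flank,
            hidden_sizes=spec.member_spec.hidden_sizes,
            n_outputs=spec.member_spec.n_outputs,
            activation=spec.member_spec.activation,
            seed=member_seed,
        )
        members.append(train_individual_net(X[idx], y[idx], member_spec, config))
    return EnsembleNet(members)


class SingleCellModule(_Averaging):
    """Per-scale ensembles trained on one gold set, averaged."""

    def __init__(self, scale_ensembles: dict[int, EnsembleNet]):
        if not scale_ensembles:
            raise ValueError("module needs at least one scale")
        self.scale_ensembles = dict(scale_ensembles)
        self.children = list(self.scale_ensembles.values())

    @property
    def scales(self) -> tuple[int, ...]:
        return tuple(self.scale_ensembles)

    @property
    def input_flank(self) -> int:
        return max(self.scales)


def train_single_cell_module(
    X: np.ndarray,
    y: np.ndarray,
    spec: SingleCellModuleSpec,
    config: TrainingConfig,
    seed: int = 0,
) -> SingleCellModule:
    """Train one ensemble per input scale on a single gold set.

    ``X`` must be at least as wide as the widest scale; each ensemble sees
    the centre crop at its own scale.
    """
    width_flank = (np.asarray(X).shape[1] - 1) // 2
    if max(spec.scales) > width_flank:
        raise ValueError(
            f"training windows (flank {width_flank}) narrower than scale {max(spec.scales)}"
        )
    ensembles = {}
    for scale in spec.scales:
        espec = EnsembleSpec(
            n_members=spec.n_members,
            member_spec=IndividualNetSpec(
                input_flank=scale,
                hidden_sizes=spec.hidden_sizes,
                activation=spec.activation,
            ),
            resample_per_class=spec.resample_per_class,
        )
        ensembles[scale] = train_ensemble(X, y, espec, config, seed=derive_seed(seed, _LEVEL_MODULE, scale))
    return SingleCellModule(ensembles)


class Component(_Averaging):
    """Average of single-cell modules, one per gold-standard set."""

    def __init__(self, modules: list[SingleCellModule]):
        if not modules:
            raise ValueError("component needs at least one module")
        scales = {m.scales for m in modules}
        if len(scales) != 1:
            raise ValueError(f"modules have mismatched scales: {scales}")
        self.children = self.modules = modules

    @property
    def scales(self) -> tuple[int, ...]:
        return self.modules[0].scales

    @property
    def input_flank(self) -> int:
        return self.modules[0].input_flank


def train_component(
    gold_sets: Sequence[tuple[np.ndarray, np.ndarray]],
    spec: SingleCellModuleSpec,
    config: TrainingConfig,
    seed: int = 0,
) -> Component:
    """Train one single-cell module per labelled gold set and average them."""
    if not gold_sets:
        raise ValueError("at least one gold set is required")
    modules = [
        train_single_cell_module(X, y, spec, config, seed=derive_seed(seed, _LEVEL_COMPONENT, i))
        for i, (X, y) in enumerate(gold_sets)
    ]
    return Component(modules)


class EditingClassifier(_Averaging):
    """The full classifier: average of the separate and pooled components.

    Either component may be omitted, in which case the model degenerates
    gracefully to the remaining one.
    """

    def __init__(self, separate: Component | None, pooled: Component | None):
        components = [c for c in (separate, pooled) if c is not None]
        if not components:
            raise ValueError("at least one component is required")
        scales = {c.scales for c in components}
        if len(scales) != 1:
            raise ValueError(f"components have mismatched scales: {scales}")
        self.separate = separate
        self.pooled = pooled
        self.children = components

    @property
    def scales(self) -> tuple[int, ...]:
        return self.children[0].scales

    @property
    def input_flank(self) -> int:
        return self.children[0].input_flank


def assemble_model(separate: Component | None, pooled: Component | None) -> EditingClassifier:
    """Combine the separate and pooled components by simple averaging."""
    return EditingClassifier(separate, pooled)


def train_full_model(
    separate_sets: Sequence[tuple[np.ndarray, np.ndarray]],
    pooled_sets: Sequence[tuple[np.ndarray, np.ndarray]],
    spec: SingleCellModuleSpec,
    config: TrainingConfig,
    seed: int = 0,
) -> EditingClassifier:
    """Train both components from their gold-set lists and assemble."""
    separate = train_component(separate_sets, spec, config, seed=derive_seed(seed, _LEVEL_COMPONENT, 0, 0)) if separate_sets else None
    pooled = train_component(pooled_sets, spec, config, seed=derive_seed(seed, _LEVEL_COMPONENT, 1, 0)) if pooled_sets else None
    return assemble_model(separate, pooled)


# ---------------------------------------------------------------------------
# Scoring and calling
# ---------------------------------------------------------------------------

def score_candidates(model, windows: Sequence[SequenceWindow]) -> list[ScoreTriple]:
    """Score a window list with any model level; order-preserving."""
    if not windows:
        return []
    X = stack_windows(windows)
    have = (X.shape[1] - 1) // 2
    need = getattr(model, "input_flank", 0)
    if have < need:
        raise ValueError(f"windows (flank {have}) narrower than the model scale {need}")
    probs = model.predict_proba(X)
    return [ScoreTriple(*map(float, p)) for p in probs]


@dataclass(frozen=True)
class CalledSite:
    """An editing call: the candidate, its editing probability, mismatch type."""

    snv: CandidateSNV
    p_editing: float
    mismatch: str

    @property
    def key(self):
        return self.snv.key


def call_editing_sites(
    scores: Sequence[ScoreTriple],
    candidates: Sequence[CandidateSNV],
    cutoff: float,
) -> list[CalledSite]:
    """Candidates whose editing probability is strictly above the cutoff.

    The cutoff is use-case dependent (it trades recall against precision);
    the comparison is strict, so cutoff 1.0 calls nothing.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    if len(scores) != len(candidates):
        raise ValueError("scores and candidates are not aligned")
    return [
        CalledSite(c, s.p_editing, str(classify_mismatch(c)))
        for s, c in zip(scores, candidates)
        if s.p_editing > cutoff
    ]


def assign_class(triple: ScoreTriple) -> ClassLabel:
    """Argmax class; exact ties prefer EDITING < SNP < OTHER."""
    return ClassLabel(int(np.argmax(triple)))


# ---------------------------------------------------------------------------
# Per-position importance
# ---------------------------------------------------------------------------

def position_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
    method: str = "permutation",
) -> np.ndarray:
    """Importance of each window position for class separation.

    ``method="permutation"`` (default, model-agnostic): shuffle one
    position's bases across examples, re-score with ``model``, and report
    the mean drop in macro one-vs-rest ROC-AUC, clipped at zero.

    ``method="gini"``: mean decrease in Gini impurity from a random-forest
    classifier fit on the flattened one-hot matrix (``model`` is ignored);
    per-position importance is the sum over the position's four channels.

    Returns a nonnegative vector of length W (the window width of ``X``).
    """
    from sklearn.metrics import roc_auc_score

    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X)
    y = np.asarray(y)
    W = X.shape[1]
    rng = np.random.default_rng(seed)

    if method == "gini":
        from sklearn.ensemble import RandomForestClassifier

        rf = RandomForestClassifier(
            n_estimators=100, random_state=derive_seed(seed, 97), n_jobs=1
        )
        rf.fit(X.reshape(X.shape[0], -1), y)
        return rf.feature_importances_.reshape(W, 4).sum(axis=1)
    if method != "permutation":
        raise ValueError(f"unknown importance method {method!r}")

    def _metric(probs: np.ndarray) -> float:
        return roc_auc_score(y, probs, multi_class="ovr", average="macro", labels=[0, 1, 2])

    baseline = _metric(model.predict_proba(X))
    scores = np.zeros(W)
    for j in range(W):
        drop = 0.0
        for _ in range(n_repeats):
            perm = rng.permutation(X.shape[0])
            Xp = X.copy()
            Xp[:, j, :] = X[perm, j, :]
            drop += baseline - _metric(model.predict_proba(Xp))
        scores[j] = drop / n_repeats
    return np.clip(scores, 0.0, None)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def _collect(node, prefix: str, manifest: dict, arrays: dict) -> None:
    if isinstance(node, IndividualNet):
        manifest[prefix] = {"kind": "net", "spec": asdict(node.spec)}
        for i, (W, b) in enumerate(zip(node.weights, node.biases)):
            arrays[f"{prefix}/W{i}"] = W
            arrays[f"{prefix}/b{i}"] = b
    elif isinstance(node, EnsembleNet):
        manifest[prefix] = {"kind": "ensemble", "n": len(node.members)}
        for i, m in enumerate(node.members):
            _collect(m, f"{prefix}/m{i}", manifest, arrays)
    elif isinstance(node, SingleCellModule):
        manifest[prefix] = {"kind": "module", "scales": list(node.scales)}
        for s, e in node.scale_ensembles.items():
            _collect(e, f"{prefix}/s{s}", manifest, arrays)
    elif isinstance(node, Component):
        manifest[prefix] = {"kind": "component", "n": len(node.modules)}
        for i, m in enumerate(node.modules):
            _collect(m, f"{prefix}/mod{i}", manifest, arrays)
    elif isinstance(node, EditingClassifier):
        manifest[prefix] = {
            "kind": "classifier",
            "has_separate": node.separate is not None,
            "has_pooled": node.pooled is not None,
        }
        if node.separate is not None:
            _collect(node.separate, f"{prefix}/sep", manifest, arrays)
        if node.pooled is not None:
            _collect(node.pooled, f"{prefix}/pool", manifest, arrays)
    else:
        raise TypeError(f"cannot serialize {type(node).__name__}")


def _rebuild(prefix: str, manifest: dict, arrays: dict):
    entry = manifest[prefix]
    kind = entry["kind"]
    if kind == "net":
        spec_d = dict(entry["spec"])
        spec_d["hidden_sizes"] = tuple(spec_d["hidden_sizes"])
        spec = IndividualNetSpec(**spec_d)
        n_layers = len(spec.hidden_sizes) + 1
        weights = [arrays[f"{prefix}/W{i}"] for i in range(n_layers)]
        biases = [arrays[f"{prefix}/b{i}"] for i in range(n_layers)]
        return IndividualNet(spec, weights, biases)
    if kind == "ensemble":
        return EnsembleNet([_rebuild(f"{prefix}/m{i}", manifest, arrays) for i in range(entry["n"])])
    if kind == "module":
        return SingleCellModule(
            {s: _rebuild(f"{prefix}/s{s}", manifest, arrays) for s in entry["scales"]}
        )
    if kind == "component":
        return Component([_rebuild(f"{prefix}/mod{i}", manifest, arrays) for i in range(entry["n"])])
    if kind == "classifier":
        sep = _rebuild(f"{prefix}/sep", manifest, arrays) if entry["has_separate"] else None
        pool = _rebuild(f"{prefix}/pool", manifest, arrays) if entry["has_pooled"] else None
        return EditingClassifier(sep, pool)
    raise ValueError(f"unknown node kind {kind!r}")


def save_model(model, path) -> None:
    """Serialize any model level to a single archive.

    The archive holds a JSON manifest (structure, specs, format version,
    spec hash) plus one binary block per weight matrix; reloading is
    bit-exact and verifies the spec hash.
    """
    manifest: dict = {}
    arrays: dict = {}
    _collect(model, "root", manifest, arrays)
    manifest_json = json.dumps(
        {"format_version": _FORMAT_VERSION, "tree": manifest}, sort_keys=True
    )
    spec_hash = hashlib.sha256(manifest_json.encode()).hexdigest()
    payload = json.dumps(
        {"format_version": _FORMAT_VERSION, "tree": manifest, "spec_hash": spec_hash},
        sort_keys=True,
    )
    np.savez_compressed(path, __manifest__=np.frombuffer(payload.encode(), dtype=np.uint8), **arrays)


def load_model(path):
    """Reload a model archive written by :func:`save_model`."""
    with np.load(path) as data:
        payload = json.loads(bytes(data["__manifest__"]).decode())
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {payload.get('format_version')}")
        manifest = payload["tree"]
        check = json.dumps(
            {"format_version": _FORMAT_VERSION, "tree": manifest}, sort_keys=True
        )
        if hashlib.sha256(check.encode()).hexdigest() != payload["spec_hash"]:
            raise ValueError("model manifest failed its integrity check")
        arrays = {k: data[k] for k in data.files if k != "__manifest__"}
    return _rebuild("root", manifest, arrays)
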