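"""Small-world neural network (SWNN) classifier.

A feedforward perceptron with 10 hidden layers of 8 neurons whose connection
topology is perturbed Watts-Strogatz style: starting from full
layer-to-next-layer connectivity, each edge is rewired with probability
``rewire_p`` to a random *forward* neuron, possibly skipping layers.  The
same cut-and-rewire move doubles as a weight-adjustment mechanism during
training: periodically the weakest fraction of connections is cut and
rewired to fresh random forward targets.

The output layer carries four neurons and a hard-limit (threshold) transfer
function at inference, so the network emits a 4-bit code; exactly four codes
map to the MI classes (0001 right hand, 0010 left hand, 0100 foot, 1000
tongue) and the remaining twelve patterns are read as the idle state.
Hard-limit units have zero gradient, so training uses a sigmoid surrogate
with per-bit cross-entropy against the class codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 4-bit output code per MI class; any other pattern decodes to "idle".
CLASS_CODES = {
    "right_hand": "0001",
    "left_hand": "0010",
    "foot": "0100",
    "tongue": "1000",
}
_CODE_TO_CLASS = {v: k for k, v in CLASS_CODES.items()}


def decode_bits(bits: str) -> str:
    """Map a 4-bit output pattern to an MI class, or ``"idle"``."""
    return _CODE_TO_CLASS.get(bits, "idle")


@dataclass
class SWNNTopology:
    """Layered DAG: nodes in topological order, masked weight matrix.

    ``mask[j, i]`` is True when an active connection i -> j exists; layer(i)
    < layer(j) always holds.  Every hidden neuron keeps at least one inbound
    and one outbound active connection (degree floor).
    """

    layer_sizes: list
    layer_of: np.ndarray       # (N,) layer index per node
    mask: np.ndarray           # N x N bool
    rewire_p: float
    rng_seed: int
    weights: np.ndarray = None
    biases: np.ndarray = None

    @property
    def n_nodes(self) -> int:
        return self.mask.shape[0]

    def layer_nodes(self, l: int) -> np.ndarray:
        return np.flatnonzero(self.layer_of == l)

    @property
    def input_nodes(self) -> np.ndarray:
        return self.layer_nodes(0)

    @property
    def output_nodes(self) -> np.ndarray:
        return self.layer_nodes(len(self.layer_sizes) - 1)

    def degree_floor_ok(self) -> bool:
        hidden = np.flatnonzero(
            (self.layer_of > 0) & (self.layer_of < len(self.layer_sizes) - 1))
        inbound = self.mask[hidden].sum(axis=1)
        outbound = self.mask[:, hidden].sum(axis=0)
        return bool(np.all(inbound >= 1) and np.all(outbound >= 1))

    def n_skip_edges(self) -> int:
        j, i = np.nonzero(self.mask)
        return int(np.sum(self.layer_of[j] - self.layer_of[i] > 1))


def build_topology(input_dim: int, rewire_p: float = 0.1, seed: int = 0, *,
                   hidden_layers: int = 10, hidden_width: int = 8,
                   n_outputs: int = 4) -> SWNNTopology:
    """Construct the layered topology and apply random forward rewiring.

    Starts fully connected layer-to-next-layer; each edge is independently
    rewired with probability ``rewire_p``: the edge (i -> j) is replaced by
    (i -> k) with k drawn uniformly from all strictly later layers.  Moves
    that would strand a neuron below the degree floor, or duplicate an
    existing edge, are retried a few times and then skipped.
    """
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    if not 0 <= rewire_p <= 1:
        raise ValueError("rewire_p must lie in [0, 1]")
    sizes = [input_dim] + [hidden_width] * hidden_layers + [n_outputs]
    layer_of = np.concatenate([np.full(s, l) for l, s in enumerate(sizes)])
    N = layer_of.size
    mask = np.zeros((N, N), dtype=bool)
    for l in range(len(sizes) - 1):
        src = np.flatnonzero(layer_of == l)
        dst = np.flatnonzero(layer_of == l + 1)
        mask[np.ix_(dst, src)] = True

    rng = np.random.default_rng(seed)
    if rewire_p > 0:
        jj, ii = np.nonzero(mask)
        for j, i in zip(jj, ii):
            if rng.random() >= rewire_p:
                continue
            for _ in range(10):
                forward = np.flatnonzero(layer_of > layer_of[i])
                k = int(rng.choice(forward))
                if k == j or mask[k, i]:
                    continue
                # cutting i->j must not strand j's inbound side
                if layer_of[j] < len(sizes) - 1 and mask[j].sum() <= 1:
                    break
                if mask[j].sum() <= 1 and layer_of[j] == len(sizes) - 1:
                    break
                mask[j, i] = False
                mask[k, i] = True
                break
    topo = SWNNTopology(sizes, layer_of, mask, rewire_p, seed)
    assert topo.degree_floor_ok()
    return topo


def _init_params(topo: SWNNTopology, rng: np.random.Generator):
    N = topo.n_nodes
    fan_in = np.maximum(topo.mask.sum(axis=1), 1)
    W = rng.standard_normal((N, N)) / np.sqrt(fan_in)[:, None]
    W[~topo.mask] = 0.0
    b = np.zeros(N)
    return W, b


def _forward(topo: SWNNTopology, W, b, X):
    """Activations (N x batch); hidden tanh, output sigmoid surrogate."""
    n_layers = len(topo.layer_sizes)
    A = np.zeros((topo.n_nodes, X.shape[0]))
    A[topo.input_nodes] = X.T
    for l in range(1, n_layers):
        rows = topo.layer_nodes(l)
        z = W[rows] @ A + b[rows][:, None]
        A[rows] = np.tanh(z) if l < n_layers - 1 else 1 / (1 + np.exp(-z))
    return A


@dataclass
class TrainingHistory:
    loss: list = field(default_factory=list)
    rewires: list = field(default_factory=list)   # epochs at which rewiring ran


class SWNN:
    """Trainable SWNN decoder with a scikit-learn-like fit/predict surface."""

    def __init__(self, input_dim: int = None, *, rewire_p: float = 0.1,
                 hidden_layers: int = 10, hidden_width: int = 8,
                 epochs: int = 300, lr: float = 0.01, seed: int = 0,
                 rewire_every: int = 50, cut_frac: float = 0.05,
                 rewire_during_training: bool = True):
        self.input_dim = input_dim
        self.rewire_p = rewire_p
        self.hidden_layers, self.hidden_width = hidden_layers, hidden_width
        self.epochs, self.lr, self.seed = epochs, lr, seed
        self.rewire_every, self.cut_frac = rewire_every, cut_frac
        self.rewire_during_training = rewire_during_training
        self.topology = None
        self.history = TrainingHistory()

    # -- training -----------------------------------------------------------

    def _targets(self, labels) -> np.ndarray:
        t = np.zeros((len(labels), 4))
        for r, lab in enumerate(labels):
            code = CLASS_CODES.get(lab)
            if code is None:
                raise ValueError(f"unknown training label {lab!r}")
            t[r] = [int(ch) for ch in code]
        return t

    def _backprop(self, topo, W, b, X, T):
        A = _forward(topo, W, b, X)
        out = topo.output_nodes
        Y = A[out].T
        eps = 1e-12
        loss = -np.mean(T * np.log(Y + eps) + (1 - T) * np.log(1 - Y + eps))
        delta = np.zeros_like(A)
        delta[out] = (Y - T).T / X.shape[0]
        for l in range(len(topo.layer_sizes) - 2, 0, -1):
            rows = topo.layer_nodes(l)
            back = W[:, rows].T @ delta
            delta[rows] = (1 - A[rows] ** 2) * back
        gW = delta @ A.T
        gW[~topo.mask] = 0.0
        gb = delta.sum(axis=1)
        gb[topo.input_nodes] = 0.0
        return loss, gW, gb

    def _cut_and_rewire(self, topo, W, rng, mW, vW):
        """Cut the weakest active edges and rewire them to random forward pairs."""
        jj, ii = np.nonzero(topo.mask)
        mags = np.abs(W[jj, ii])
        n_cut = int(np.floor(self.cut_frac * len(mags)))
        if n_cut == 0:
            return
        order = np.argsort(mags)
        cut = 0
        last = len(topo.layer_sizes) - 1
        for e in order:
            if cut >= n_cut:
                break
            j, i = jj[e], ii[e]
            # respect degree floors on both endpoints
            if topo.layer_of[j] != last and topo.mask[j].sum() <= 1:
                continue
            if topo.layer_of[i] != 0 and topo.mask[:, i].sum() <= 1:
                continue
            candidates_src = np.flatnonzero(topo.layer_of < last)
            for _ in range(10):
                i2 = int(rng.choice(candidates_src))
                fwd = np.flatnonzero(topo.layer_of > topo.layer_of[i2])
                j2 = int(rng.choice(fwd))
                if not topo.mask[j2, i2]:
                    topo.mask[j, i] = False
                    topo.mask[j2, i2] = True
                    W[j, i] = 0.0
                    W[j2, i2] = 0.01 * rng.standard_normal()
                    mW[j2, i2] = vW[j2, i2] = 0.0
                    cut += 1
                    break

    def fit(self, X, labels) -> "SWNN":
        X = np.asarray(X, float)
        labels = list(labels)
        if len(set(labels)) < 2:
            raise ValueError("need at least 2 classes in training data")
        if self.input_dim is None:
            self.input_dim = X.shape[1]
        rng = np.random.default_rng(self.seed)
        topo = build_topology(self.input_dim, self.rewire_p,
                              seed=int(rng.integers(2 ** 31)),
                              hidden_layers=self.hidden_layers,
                              hidden_width=self.hidden_width)
        W, b = _init_params(topo, rng)
        T = self._targets(labels)
        mW, vW = np.zeros_like(W), np.zeros_like(W)
        mb, vb = np.zeros_like(b), np.zeros_like(b)
        lr = self.lr
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        self.history = TrainingHistory()
        failures = 0
        step = 0
        epoch = 0
        while epoch < self.epochs:
            loss, gW, gb = self._backprop(topo, W, b, X, T)
            if not np.isfinite(loss):
                failures += 1
                if failures >= 3:
                    raise RuntimeError(
                        f"training diverged (non-finite loss); history="
                        f"{self.history.loss[-5:]}")
                lr *= 0.5
                continue
            step += 1
            for g, p, m, v in ((gW, W, mW, vW), (gb, b, mb, vb)):
                m *= beta1; m += (1 - beta1) * g
                v *= beta2; v += (1 - beta2) * g * g
                mhat = m / (1 - beta1 ** step)
                vhat = v / (1 - beta2 ** step)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
            W[~topo.mask] = 0.0
            self.history.loss.append(float(loss))
            epoch += 1
            if (self.rewire_during_training and self.rewire_every > 0
                    and epoch % self.rewire_every == 0 and epoch < self.epochs):
                self._cut_and_rewire(topo, W, rng, mW, vW)
                self.history.rewires.append(epoch)
                assert topo.degree_floor_ok()
        topo.weights, topo.biases = W, b
        self.topology = topo
        return self

    # -- inference ----------------------------------------------------------

    def _check_fitted(self):
        if self.topology is None or self.topology.weights is None:
            raise RuntimeError("SWNN is not fitted")

    def activations(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, float))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        if X.shape[1] != self.input_dim:
            raise ValueError(f"feature length {X.shape[1]} != input_dim "
                             f"{self.input_dim}")
        topo = self.topology
        A = _forward(topo, topo.weights, topo.biases, X)
        return A[topo.output_nodes].T

    def predict_bits(self, X) -> list:
        return [bits_from_activations(a) for a in self.activations(X)]

    def predict(self, X) -> list:
        """Hard-limit decode: 4-bit code -> MI class, non-class codes -> idle."""
        return [decode_bits(bits) for bits in self.predict_bits(X)]


def bits_from_activations(act) -> str:
    """Hard-limit transfer: threshold the 4 output activations at 0.5."""
    act = np.asarray(act, float).ravel()
    if act.size != 4:
        raise ValueError("expected 4 output activations")
    return "".join("1" if a > 0.5 else "0" for a in act)


def predict_label(model: SWNN, feature) -> str:
    values = feature.values if hasattr(feature, "values") else feature
    return model.predict(np.atleast_2d(values))[0]


def graph_metrics(topo: SWNNTopology) -> dict:
    """Characteristic path length & clustering of the undirected projection."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(range(topo.n_nodes))
    jj, ii = np.nonzero(topo.mask)
    G.add_edges_from(zip(ii.tolist(), jj.tolist()))
    if not nx.is_connected(G):
        comp = max(nx.connected_components(G), key=len)
        G = G.subgraph(comp)
    return {
        "path_length": nx.average_shortest_path_length(G),
        "clustering": nx.average_clustering(G),
    }
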