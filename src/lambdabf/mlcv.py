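"""Machine-learned collective variables: LDA and Deep-LDA.

Two conformational states (Apo = class 0, Holo = class 1) observed in
unbiased runs are summarised by geometric descriptors (distances and
angles). Linear discriminant analysis finds the direction w maximising
Fisher's ratio (wᵀS_b w)/(wᵀS_w w) of between- to within-class scatter;
the CV is the projection s = wᵀd. Deep-LDA feeds the descriptors through
a small fully-connected network and performs the LDA in its last hidden
layer, giving a nonlinear CV s = wᵀh(d). For use in biased sampling the
output is smoothed by the cubic transform s_w = s + s³.

Scatter-matrix convention: per-class mean-centred *sums* (not divided by
the frame count), the classical LDA definition; with ``balanced=True``
each class sum is rescaled to the mean class size so gross frame-count
imbalance cannot dominate the pooled scatter.

The network is a plain numpy implementation (tanh layers, full-batch
Adam); the Fisher objective J = Δμᵀ(S_w+δI)⁻¹Δμ has a closed-form
gradient with respect to the hidden activations, which is backpropagated
by hand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


class DegenerateClassesError(ValueError):
    """Classes indistinguishable (or one empty): discriminant undefined."""


# ---------------------------------------------------------------------------
# descriptors


@dataclass(frozen=True)
class DescriptorDefinition:
    kind: str                      # "distance" | "angle"
    atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("distance", "angle"):
            raise ValueError("descriptor kind must be 'distance' or 'angle'")
        need = 2 if self.kind == "distance" else 3
        if len(self.atoms) != need:
            raise ValueError(f"{self.kind} descriptor needs {need} atoms")


def compute_descriptors(frames: np.ndarray,
                        definitions: list[DescriptorDefinition]) -> np.ndarray:
    """Per-frame descriptor matrix (F × N_d); angles in radians ∈ [0, π]."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    cols = []
    for dd in definitions:
        if max(dd.atoms) >= frames.shape[1]:
            raise IndexError(f"descriptor atom index {max(dd.atoms)} out of "
                             "range")
        if dd.kind == "distance":
            i, j = dd.atoms
            cols.append(np.linalg.norm(frames[:, j] - frames[:, i], axis=1))
        else:
            i, j, k = dd.atoms
            a = frames[:, i] - frames[:, j]
            b = frames[:, k] - frames[:, j]
            na = np.linalg.norm(a, axis=1)
            nb = np.linalg.norm(b, axis=1)
            c = np.einsum("ij,ij->i", a, b) / np.maximum(na * nb, 1e-12)
            cols.append(np.arccos(np.clip(c, -1.0, 1.0)))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# scatter matrices and closed-form LDA


def scatter_matrices(x_apo: np.ndarray, x_holo: np.ndarray,
                     balanced: bool = True):
    """Within- and between-class scatter (S_w, S_b) for the two-class case.

    S_w is the sum of per-class mean-centred scatter sums; S_b the outer
    product of the class-mean difference. ``balanced`` rescales each class
    sum by (mean class size / class size).
    """
    x_apo = np.asarray(x_apo, dtype=float)
    x_holo = np.asarray(x_holo, dtype=float)
    if len(x_apo) < 2 or len(x_holo) < 2:
        raise DegenerateClassesError("need ≥2 frames per class")
    mu0 = x_apo.mean(axis=0)
    mu1 = x_holo.mean(axis=0)
    c0 = x_apo - mu0
    c1 = x_holo - mu1
    s0 = c0.T @ c0
    s1 = c1.T @ c1
    if balanced:
        nbar = 0.5 * (len(x_apo) + len(x_holo))
        s0 = s0 * (nbar / len(x_apo))
        s1 = s1 * (nbar / len(x_holo))
    sw = s0 + s1
    dmu = mu1 - mu0
    sb = np.outer(dmu, dmu)
    return sw, sb


def fisher_ratio(w: np.ndarray, sw: np.ndarray, sb: np.ndarray) -> float:
    w = np.asarray(w, dtype=float)
    return float((w @ sb @ w) / (w @ sw @ w))


def default_regularization(sw: np.ndarray) -> float:
    nd = sw.shape[0]
    return 1e-6 * float(np.trace(sw)) / nd


@dataclass
class LdaModel:
    """Fitted (Deep-)LDA collective variable.

    ``layers`` is empty for plain LDA; otherwise a list of (W, b) tanh
    layers applied before the discriminant projection. ``w`` is unit-norm
    with sign fixed so the Holo class projects positive. The ``cubic``
    flag enables the s_w = s + s³ output transform of
    :func:`evaluate_cv`.
    """

    w: np.ndarray
    mean_apo: np.ndarray
    mean_holo: np.ndarray
    sw: np.ndarray
    sb: np.ndarray
    delta: float
    layers: list = field(default_factory=list)
    activation: str = "tanh"
    input_mean: np.ndarray | None = None
    input_scale: np.ndarray | None = None
    cubic: bool = True
    loss_history: np.ndarray | None = None

    @property
    def n_inputs(self) -> int:
        if self.layers:
            return self.layers[0][0].shape[1]
        return len(self.w)

    def hidden(self, d: np.ndarray) -> np.ndarray:
        h = np.atleast_2d(np.asarray(d, dtype=float))
        if h.shape[1] != self.n_inputs:
            raise ValueError(
                f"descriptor vector length {h.shape[1]} != {self.n_inputs}")
        if self.input_mean is not None:
            h = (h - self.input_mean) / self.input_scale
        for wl, bl in self.layers:
            z = h @ wl.T + bl
            h = np.tanh(z) if self.activation == "tanh" else z
        return h

    def project(self, d: np.ndarray) -> np.ndarray:
        return self.hidden(d) @ self.w

    def fisher(self) -> float:
        return fisher_ratio(self.w, self.sw + self.delta * np.eye(
            len(self.w)), self.sb)

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "w": self.w.tolist(),
            "mean_apo": self.mean_apo.tolist(),
            "mean_holo": self.mean_holo.tolist(),
            "sw": self.sw.tolist(),
            "sb": self.sb.tolist(),
            "delta": self.delta,
            "cubic": self.cubic,
            "activation": self.activation,
            "layers": [[wl.tolist(), bl.tolist()] for wl, bl in self.layers],
            "input_mean": (None if self.input_mean is None
                           else self.input_mean.tolist()),
            "input_scale": (None if self.input_scale is None
                            else self.input_scale.tolist()),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LdaModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            w=np.asarray(obj["w"]),
            mean_apo=np.asarray(obj["mean_apo"]),
            mean_holo=np.asarray(obj["mean_holo"]),
            sw=np.asarray(obj["sw"]),
            sb=np.asarray(obj["sb"]),
            delta=float(obj["delta"]),
            cubic=bool(obj["cubic"]),
            activation=obj.get("activation", "tanh"),
            layers=[(np.asarray(wl), np.asarray(bl))
                    for wl, bl in obj["layers"]],
            input_mean=(None if obj["input_mean"] is None
                        else np.asarray(obj["input_mean"])),
            input_scale=(None if obj["input_scale"] is None
                         else np.asarray(obj["input_scale"])),
        )


def fit_lda(x_apo: np.ndarray, x_holo: np.ndarray,
            regularization: float | None = None,
            balanced: bool = True) -> LdaModel:
    """Closed-form two-class LDA: w ∝ (S_w + δI)⁻¹(μ_Holo − μ_Apo).

    Raises :class:`DegenerateClassesError` when the class means coincide
    (Fisher ratio 0, direction undefined) and a conditioning error when
    S_w is singular and δ = 0.
    """
    x_apo = np.asarray(x_apo, dtype=float)
    x_holo = np.asarray(x_holo, dtype=float)
    sw, sb = scatter_matrices(x_apo, x_holo, balanced=balanced)
    delta = (default_regularization(sw) if regularization is None
             else float(regularization))
    dmu = x_holo.mean(axis=0) - x_apo.mean(axis=0)
    if np.linalg.norm(dmu) < 1e-12:
        raise DegenerateClassesError(
            "identical class means; Fisher ratio is 0 and w is undefined")
    m = sw + delta * np.eye(sw.shape[0])
    try:
        w = np.linalg.solve(m, dmu)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular within-class scatter; pass a regularization δ > 0"
        ) from err
    w = w / np.linalg.norm(w)
    if w @ dmu < 0:
        w = -w
    return LdaModel(w=w, mean_apo=x_apo.mean(axis=0),
                    mean_holo=x_holo.mean(axis=0), sw=sw, sb=sb,
                    delta=delta)


# ---------------------------------------------------------------------------
# Deep-LDA


def _fisher_objective_grad(h0: np.ndarray, h1: np.ndarray, delta: float):
    """J = Δμᵀ(S_w+δI)⁻¹Δμ on hidden activations, with dJ/dh per frame."""
    mu0 = h0.mean(axis=0)
    mu1 = h1.mean(axis=0)
    dmu = mu1 - mu0
    c0 = h0 - mu0
    c1 = h1 - mu1
    sw = c0.T @ c0 + c1.T @ c1
    m = sw + delta * np.eye(sw.shape[0])
    v = np.linalg.solve(m, dmu)
    j = float(dmu @ v)
    # dJ/dΔμ = 2v ; dJ/dS_w = −v vᵀ
    g0 = -2.0 * v / len(h0) - 2.0 * (c0 @ v)[:, None] * v
    g1 = 2.0 * v / len(h1) - 2.0 * (c1 @ v)[:, None] * v
    return j, g0, g1, v, m


def fit_deep_lda(x_apo: np.ndarray, x_holo: np.ndarray,
                 hidden: tuple[int, ...] = (24, 12), seed: int = 0,
                 epochs: int = 500, learning_rate: float = 5e-3,
                 regularization: float | None = None,
                 activation: str = "tanh") -> LdaModel:
    """Train a tanh network so LDA in its last layer maximises Fisher's ratio.

    Full-batch Adam on −J with J = Δμᵀ(S_w+δI)⁻¹Δμ evaluated on the
    hidden activations; the final discriminant w comes from closed-form
    LDA on those activations. Deterministic for a given seed.
    """
    x_apo = np.asarray(x_apo, dtype=float)
    x_holo = np.asarray(x_holo, dtype=float)
    if len(x_apo) < 2 or len(x_holo) < 2:
        raise DegenerateClassesError("need ≥2 frames per class")
    nd = x_apo.shape[1]
    mean = np.vstack([x_apo, x_holo]).mean(axis=0)
    scale = np.vstack([x_apo, x_holo]).std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    a0 = (x_apo - mean) / scale
    a1 = (x_holo - mean) / scale

    rng = np.random.default_rng(seed)
    sizes = [nd, *hidden]
    params = []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        params.append([rng.uniform(-lim, lim, (fan_out, fan_in)),
                       np.zeros(fan_out)])

    adam_m = [[np.zeros_like(w), np.zeros_like(b)] for w, b in params]
    adam_v = [[np.zeros_like(w), np.zeros_like(b)] for w, b in params]
    b1, b2, eps_adam = 0.9, 0.999, 1e-8

    if activation not in ("tanh", "linear"):
        raise ValueError("activation must be 'tanh' or 'linear'")

    def forward(x):
        acts = [x]
        for w, b in params:
            z = acts[-1] @ w.T + b
            acts.append(np.tanh(z) if activation == "tanh" else z)
        return acts

    n0, n1 = len(a0), len(a1)
    losses = []
    delta_train = None
    for epoch in range(epochs):
        acts0 = forward(a0)
        acts1 = forward(a1)
        h0, h1 = acts0[-1], acts1[-1]
        sw_h, _ = scatter_matrices(h0, h1, balanced=False)
        delta_train = (default_regularization(sw_h) + 1e-8
                       if regularization is None else float(regularization))
        j, g0, g1, _, _ = _fisher_objective_grad(h0, h1, delta_train)
        if not np.isfinite(j):
            raise RuntimeError(f"non-finite Fisher objective at epoch "
                               f"{epoch}")
        losses.append(-j)
        # backprop of dL/dh = −dJ/dh through the tanh stack
        d0, d1 = -g0, -g1
        grads = []
        for li in range(len(params) - 1, -1, -1):
            w, b = params[li]
            if activation == "tanh":
                z0 = d0 * (1.0 - acts0[li + 1] ** 2)
                z1 = d1 * (1.0 - acts1[li + 1] ** 2)
            else:
                z0, z1 = d0, d1
            gw = z0.T @ acts0[li] + z1.T @ acts1[li]
            gb = z0.sum(axis=0) + z1.sum(axis=0)
            grads.append((gw, gb))
            d0 = z0 @ w
            d1 = z1 @ w
        grads.reverse()
        t = epoch + 1
        for li, ((gw, gb), (w, b)) in enumerate(zip(grads, params)):
            for slot, g in ((0, gw), (1, gb)):
                adam_m[li][slot] = b1 * adam_m[li][slot] + (1 - b1) * g
                adam_v[li][slot] = b2 * adam_v[li][slot] + (1 - b2) * g * g
                mhat = adam_m[li][slot] / (1 - b1 ** t)
                vhat = adam_v[li][slot] / (1 - b2 ** t)
                params[li][slot] = params[li][slot] - learning_rate * mhat / (
                    np.sqrt(vhat) + eps_adam)

    h0 = forward(a0)[-1]
    h1 = forward(a1)[-1]
    head = fit_lda(h0, h1, regularization=regularization, balanced=True)
    return LdaModel(w=head.w, mean_apo=h0.mean(axis=0),
                    mean_holo=h1.mean(axis=0), sw=head.sw, sb=head.sb,
                    delta=head.delta,
                    layers=[(w.copy(), b.copy()) for w, b in params],
                    activation=activation,
                    input_mean=mean, input_scale=scale,
                    loss_history=np.asarray(losses))


def evaluate_cv(model: LdaModel, d: np.ndarray):
    """CV value(s) for a descriptor vector: (s, s_w) with s_w = s + s³."""
    s = model.project(d)
    if np.isscalar(d) or np.asarray(d).ndim == 1:
        s = float(s[0])
        return s, (s + s ** 3 if model.cubic else s)
    sw = s + s ** 3 if model.cubic else s
    return s, sw


class LdaCv:
    """Adapter exposing an LdaModel over descriptors as a 1D dynamic CV.

    Gradients are assembled by the chain rule through the descriptor
    geometry and (for Deep-LDA) the tanh network Jacobian; the cubic
    transform contributes the factor 1 + 3s².
    """

    def __init__(self, model: LdaModel,
                 definitions: list[DescriptorDefinition],
                 use_cubic: bool | None = None):
        self.model = model
        self.definitions = definitions
        self.use_cubic = model.cubic if use_cubic is None else use_cubic

    def value(self, positions: np.ndarray) -> float:
        d = compute_descriptors(positions[None], self.definitions)[0]
        s, s_w = evaluate_cv(self.model, d)
        return s_w if self.use_cubic else s

    def _ds_dd(self, d: np.ndarray) -> np.ndarray:
        m = self.model
        if not m.layers:
            return m.w
        h = (d - m.input_mean) / m.input_scale
        jac = np.diag(1.0 / m.input_scale)
        for wl, bl in m.layers:
            z = h @ wl.T + bl
            if m.activation == "tanh":
                z = np.tanh(z)
                jac = ((1.0 - z ** 2)[:, None] * wl) @ jac
            else:
                jac = wl @ jac
            h = z
        return m.w @ jac

    def gradient(self, positions: np.ndarray) -> np.ndarray:
        d = compute_descriptors(positions[None], self.definitions)[0]
        ds_dd = self._ds_dd(d)
        if self.use_cubic:
            s = float(self.model.project(d)[0])
            ds_dd = ds_dd * (1.0 + 3.0 * s * s)
        g = np.zeros_like(positions)
        for weight, dd in zip(ds_dd, self.definitions):
            if dd.kind == "distance":
                i, j = dd.atoms
                v = positions[j] - positions[i]
                r = max(float(np.linalg.norm(v)), 1e-12)
                g[j] += weight * v / r
                g[i] -= weight * v / r
            else:
                i, j, k = dd.atoms
                a = positions[i] - positions[j]
                b = positions[k] - positions[j]
                na = max(float(np.linalg.norm(a)), 1e-12)
                nb = max(float(np.linalg.norm(b)), 1e-12)
                c = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
                s_ = np.sqrt(max(1.0 - c * c, 1e-12))
                gi = -(1.0 / s_) * (b / (na * nb) - c * a / (na * na))
                gk = -(1.0 / s_) * (a / (na * nb) - c * b / (nb * nb))
                g[i] += weight * gi
                g[k] += weight * gk
                g[j] -= weight * (gi + gk)
        return g
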