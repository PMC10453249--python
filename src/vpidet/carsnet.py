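"""Cross-attention residual Siamese network (CARS-Net) for vowel classification.

Two weight-shared residual branches consume the nasal- and oral-channel
spectrograms of one vowel.  Each residual block carries a cross-attention
(CA) coupling: the two branch inputs are concatenated along channels,
globally average-pooled, passed through a shared fully connected layer with a
rectifier to give one channel-weight vector, which scales the conv-path
output of *both* branches before the skip addition:

    F_{i+1} = skip(F_i) + W_i ⊙ conv_path(F_i)

The classifier is a fully connected softmax head on the flattened difference
of the two final feature maps, and training minimizes cross-entropy plus a
contrastive term on the Euclidean distance between the flattened maps
(margin 2, labels y = 1 for VPI).

Everything here is plain numpy with hand-derived gradients; a finite-
difference check in the test suite validates the backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ------------------------------------------------------------------ configs


@dataclass
class VowelNetConfig:
    widths: tuple[int, ...] = (64, 128, 256, 512)
    blocks: tuple[int, ...] = (2, 2, 2, 2)
    stage_strides: tuple[int, ...] = (1, 2, 2, 2)
    stem: str = "default"       # "default": 7x7/2 conv + 3x3/2 pool; "small": 3x3/1 + 2x2/2
    side: int = 64
    use_ca: bool = True
    use_contrastive: bool = True
    margin: float = 2.0
    epochs: int = 100
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.widths, self.widths[1:])):
            raise ValueError("stage widths must be strictly increasing")

    @classmethod
    def small(cls, **overrides) -> "VowelNetConfig":
        """Desk-scale preset: 3x3 stride-1 stem, widths [8, 16, 32, 64],
        one block per stage, every stage stride 2."""
        cfg = cls(widths=(8, 16, 32, 64), blocks=(1, 1, 1, 1),
                  stage_strides=(2, 2, 2, 2), stem="small")
        return replace(cfg, **overrides)


@dataclass
class EmbeddingPair:
    F_n_final: np.ndarray       # (C, H, W)
    F_o_final: np.ndarray
    d: float                    # Euclidean distance between flattened maps
    margin: float = 2.0


@dataclass
class LossValues:
    loss1: float                # cross-entropy
    loss2: float                # contrastive term
    total: float
    y: np.ndarray
    P: np.ndarray               # predicted VPI probability per sample


# ------------------------------------------------------------- primitive ops


def conv_forward(x, w, b, stride: int, pad: int):
    N, C, H, W = x.shape
    F, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    out = np.einsum("nchwkl,fckl->nfhw", win, w, optimize=True)
    out += b[None, :, None, None]
    return out, (win, x.shape, w, stride, pad)


def conv_backward(dout, cache):
    win, xshape, w, stride, pad = cache
    N, C, H, W = xshape
    F, _, kh, kw = w.shape
    Ho, Wo = dout.shape[2], dout.shape[3]
    dw = np.einsum("nchwkl,nfhw->fckl", win, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dcols = np.einsum("nfhw,fckl->nchwkl", dout, w, optimize=True)
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad))
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += \
                dcols[:, :, :, :, i, j]
    dx = dxp[:, :, pad:pad + H, pad:pad + W] if pad else dxp
    return dx, dw, db


def maxpool_forward(x, k: int, stride: int, pad: int):
    N, C, H, W = x.shape
    xp = (np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                 constant_values=-np.inf) if pad else x)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = win.reshape(*win.shape[:4], k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, (x.shape, idx, k, stride, pad)


def maxpool_backward(dout, cache):
    xshape, idx, k, stride, pad = cache
    N, C, H, W = xshape
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad))
    n, c, ho, wo = np.indices(dout.shape)
    hi = ho * stride + idx // k
    wi = wo * stride + idx % k
    np.add.at(dxp, (n, c, hi, wi), dout)
    return dxp[:, :, pad:pad + H, pad:pad + W] if pad else dxp


# ------------------------------------------------------------------- losses


def contrastive_loss(d, y, margin: float = 2.0):
    """y * d^2 + (1 - y) * max(margin - d, 0)^2, elementwise; y = 1 for VPI.

    Nonnegative by construction: same-class (VPI) pairs are pulled together,
    control pairs pushed beyond the margin.
    """
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    y = np.asarray(y, dtype=np.float64)
    return y * d ** 2 + (1.0 - y) * np.maximum(margin - d, 0.0) ** 2


def cross_entropy(P_vpi, y):
    """Binary cross-entropy with probability clipping to [1e-12, 1 - 1e-12]."""
    P = np.clip(np.asarray(P_vpi, dtype=np.float64), 1e-12, 1.0 - 1e-12)
    y = np.asarray(y, dtype=np.float64)
    return -(y * np.log(P) + (1.0 - y) * np.log(1.0 - P))


def classify_vowel(emb: EmbeddingPair, head_w: np.ndarray,
                   head_b: np.ndarray) -> tuple[float, float]:
    """Softmax head over the flattened difference map: (P_control, P_vpi)."""
    diff = (emb.F_n_final - emb.F_o_final).ravel()
    if diff.size != head_w.shape[0]:
        raise ValueError("head input length mismatch")
    logits = diff @ head_w + head_b
    e = np.exp(logits - logits.max())
    p = e / e.sum()
    return float(p[0]), float(p[1])


# ------------------------------------------------------------------ network


class CARSNet:
    """Weight-shared two-branch residual network with cross-attention blocks."""

    def __init__(self, cfg: VowelNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {}
        self._block_specs: list[tuple[str, int, int, int, bool]] = []

        def he_conv(name, cout, cin, k):
            self.params[name + "_w"] = rng.normal(
                0.0, np.sqrt(2.0 / (cin * k * k)), size=(cout, cin, k, k))
            self.params[name + "_b"] = np.zeros(cout)

        def he_fc(name, nin, nout):
            self.params[name + "_w"] = rng.normal(
                0.0, np.sqrt(2.0 / nin), size=(nin, nout))
            self.params[name + "_b"] = np.zeros(nout)

        w0 = cfg.widths[0]
        if cfg.stem == "default":
            he_conv("stem", w0, 1, 7)
            self._stem = (2, 3, 3, 2, 1)    # conv stride, pad; pool k, stride, pad
            side = cfg.side // 4
        elif cfg.stem == "small":
            he_conv("stem", w0, 1, 3)
            self._stem = (1, 1, 2, 2, 0)
            side = cfg.side // 2
        else:
            raise ValueError(f"unknown stem {cfg.stem!r}")

        cin = w0
        for s, (width, nblocks, stride0) in enumerate(
                zip(cfg.widths, cfg.blocks, cfg.stage_strides)):
            for b in range(nblocks):
                stride = stride0 if b == 0 else 1
                name = f"s{s}b{b}"
                proj = (stride != 1) or (cin != width)
                he_conv(name + "_c1", width, cin, 3)
                he_conv(name + "_c2", width, width, 3)
                if proj:
                    he_conv(name + "_p", width, cin, 1)
                if cfg.use_ca:
                    he_fc(name + "_a", 2 * cin, width)
                self._block_specs.append((name, cin, width, stride, proj))
                cin = width
                side = -(-side // stride)   # ceil division with pad-1 3x3 convs
        self.final_shape = (cin, side, side)
        self.flat_dim = cin * side * side
        he_fc("head", self.flat_dim, 2)

    # ---------------------------------------------------------------- forward

    def _stem_forward(self, x):
        cs, cp, pk, ps, pp = self._stem
        h, c1 = conv_forward(x, self.params["stem_w"], self.params["stem_b"], cs, cp)
        mask = h > 0
        a = h * mask
        out, c2 = maxpool_forward(a, pk, ps, pp)
        return out, (c1, mask, c2)

    def _stem_backward(self, dout, cache, grads):
        c1, mask, c2 = cache
        da = maxpool_backward(dout, c2)
        dh = da * mask
        dx, dw, db = conv_backward(dh, c1)
        grads["stem_w"] += dw
        grads["stem_b"] += db
        return dx

    def block_forward(self, xn, xo, name: str):
        """One CA residual block applied to both branch feature maps."""
        _, cin, width, stride, proj = next(
            s for s in self._block_specs if s[0] == name)
        p = self.params
        cache: dict = {"name": name, "proj": proj, "stride": stride}

        branch = {}
        for tag, x in (("n", xn), ("o", xo)):
            h1, cc1 = conv_forward(x, p[name + "_c1_w"], p[name + "_c1_b"], stride, 1)
            m1 = h1 > 0
            f, cc2 = conv_forward(h1 * m1, p[name + "_c2_w"], p[name + "_c2_b"], 1, 1)
            branch[tag] = (cc1, m1, cc2, f)
        fn, fo = branch["n"][3], branch["o"][3]

        if self.cfg.use_ca:
            g = np.concatenate([xn.mean(axis=(2, 3)), xo.mean(axis=(2, 3))], axis=1)
            z = g @ p[name + "_a_w"] + p[name + "_a_b"]
            a = np.maximum(z, 0.0)
            Mn = fn * a[:, :, None, None]
            Mo = fo * a[:, :, None, None]
            cache["att"] = (g, z, a, xn.shape)
        else:
            Mn, Mo = fn, fo

        if proj:
            sn, cpn = conv_forward(xn, p[name + "_p_w"], p[name + "_p_b"], stride, 0)
            so, cpo = conv_forward(xo, p[name + "_p_w"], p[name + "_p_b"], stride, 0)
            cache["proj_c"] = (cpn, cpo)
        else:
            sn, so = xn, xo
        cache["branch"] = branch
        return sn + Mn, so + Mo, cache

    def block_backward(self, dn, do, cache, grads):
        name, proj = cache["name"], cache["proj"]
        branch = cache["branch"]
        fn, fo = branch["n"][3], branch["o"][3]

        if proj:
            cpn, cpo = cache["proj_c"]
            dxn, dpw, dpb = conv_backward(dn, cpn)
            dxo, dpw2, dpb2 = conv_backward(do, cpo)
            grads[name + "_p_w"] += dpw + dpw2
            grads[name + "_p_b"] += dpb + dpb2
        else:
            dxn, dxo = dn.copy(), do.copy()

        if self.cfg.use_ca:
            g, z, a, xshape = cache["att"]
            aw = self.params[name + "_a_w"]
            dfn = dn * a[:, :, None, None]
            dfo = do * a[:, :, None, None]
            da = (dn * fn).sum(axis=(2, 3)) + (do * fo).sum(axis=(2, 3))
            dz = da * (z > 0)
            grads[name + "_a_w"] += g.T @ dz
            grads[name + "_a_b"] += dz.sum(axis=0)
            dg = dz @ aw.T
            cin = xshape[1]
            hw = xshape[2] * xshape[3]
            dxn += (dg[:, :cin] / hw)[:, :, None, None]
            dxo += (dg[:, cin:] / hw)[:, :, None, None]
        else:
            dfn, dfo = dn, do

        for tag, df, acc in (("n", dfn, "dxn"), ("o", dfo, "dxo")):
            cc1, m1, cc2, _ = branch[tag]
            dh1a, dw2, db2 = conv_backward(df, cc2)
            dh1 = dh1a * m1
            dx, dw1, db1 = conv_backward(dh1, cc1)
            grads[name + "_c2_w"] += dw2
            grads[name + "_c2_b"] += db2
            grads[name + "_c1_w"] += dw1
            grads[name + "_c1_b"] += db1
            if tag == "n":
                dxn += dx
            else:
                dxo += dx
        return dxn, dxo

    def forward_features(self, Xn, Xo):
        """Run both branches; returns final maps and the backward cache."""
        xn = Xn[:, None, :, :].astype(np.float64)
        xo = Xo[:, None, :, :].astype(np.float64)
        xn, sc_n = self._stem_forward(xn)
        xo, sc_o = self._stem_forward(xo)
        caches = []
        for spec in self._block_specs:
            xn, xo, c = self.block_forward(xn, xo, spec[0])
            caches.append(c)
        return xn, xo, (sc_n, sc_o, caches)

    def backward_features(self, dfn, dfo, cache, grads):
        sc_n, sc_o, caches = cache
        for c in reversed(caches):
            dfn, dfo = self.block_backward(dfn, dfo, c, grads)
        self._stem_backward(dfn, sc_n, grads)
        self._stem_backward(dfo, sc_o, grads)

    def embed(self, S_n: np.ndarray, S_o: np.ndarray) -> EmbeddingPair:
        fn, fo, _ = self.forward_features(S_n[None], S_o[None])
        d = float(np.linalg.norm((fn - fo).ravel()))
        return EmbeddingPair(F_n_final=fn[0], F_o_final=fo[0], d=d,
                             margin=self.cfg.margin)

    def predict_proba(self, Xn, Xo) -> np.ndarray:
        """(N, 2) probabilities [P_control, P_vpi]."""
        fn, fo, _ = self.forward_features(Xn, Xo)
        diff = (fn - fo).reshape(fn.shape[0], -1)
        logits = diff @ self.params["head_w"] + self.params["head_b"]
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    # ------------------------------------------------------- loss & gradients

    def loss_and_grads(self, Xn, Xo, y):
        """Mean total loss over a batch and gradients for every parameter."""
        N = Xn.shape[0]
        y = np.asarray(y, dtype=np.float64)
        fn, fo, cache = self.forward_features(Xn, Xo)
        flat_n = fn.reshape(N, -1)
        flat_o = fo.reshape(N, -1)
        diff = flat_n - flat_o
        logits = diff @ self.params["head_w"] + self.params["head_b"]
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        P_vpi = probs[:, 1]

        loss1 = float(cross_entropy(P_vpi, y).mean())
        d = np.linalg.norm(diff, axis=1)
        if self.cfg.use_contrastive:
            loss2 = float(contrastive_loss(d, y, self.cfg.margin).mean())
        else:
            loss2 = 0.0

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        onehot = np.stack([1.0 - y, y], axis=1)
        dlogits = (probs - onehot) / N
        grads["head_w"] += diff.T @ dlogits
        grads["head_b"] += dlogits.sum(axis=0)
        ddiff = dlogits @ self.params["head_w"].T
        if self.cfg.use_contrastive:
            dL_dd = (2.0 * y * d
                     - 2.0 * (1.0 - y) * np.maximum(self.cfg.margin - d, 0.0)) / N
            dsafe = np.where(d > 1e-12, dL_dd / np.maximum(d, 1e-12), 0.0)
            ddiff = ddiff + dsafe[:, None] * diff
        self.backward_features(ddiff.reshape(fn.shape), (-ddiff).reshape(fo.shape),
                               cache, grads)
        lv = LossValues(loss1=loss1, loss2=loss2, total=loss1 + loss2, y=y, P=P_vpi)
        return lv, grads


# ----------------------------------------------------------------- training


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)

    def final(self) -> dict:
        return self.epochs[-1]


def _labels_to_y(labels) -> np.ndarray:
    return np.array([1.0 if lab == "vpi" else 0.0 for lab in labels])


def train_vowel_model(train, cfg: VowelNetConfig) -> tuple[CARSNet, TrainHistory]:
    """Train CARS-Net with Adam on (SpectrogramPair, label) examples.

    All randomness (He initialization, epoch shuffling) derives from
    ``cfg.seed``; identical seed and data give bit-identical results.
    """
    pairs = [p for p, _ in train]
    labels = [lab for _, lab in train]
    y = _labels_to_y(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes in the training set")
    Xn = np.stack([p.S_n for p in pairs])
    Xo = np.stack([p.S_o for p in pairs])

    net = CARSNet(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in net.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    hist = TrainHistory()
    N = len(pairs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(N)
        tot1 = tot2 = 0.0
        correct = 0
        for start in range(0, N, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            lv, grads = net.loss_and_grads(Xn[idx], Xo[idx], y[idx])
            if not np.isfinite(lv.total):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={lv.total}")
            t += 1
            for k in net.params:
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                mhat = m[k] / (1 - b1 ** t)
                vhat = v[k] / (1 - b2 ** t)
                net.params[k] -= cfg.lr * mhat / (np.sqrt(vhat) + eps)
            tot1 += lv.loss1 * len(idx)
            tot2 += lv.loss2 * len(idx)
            correct += int(((lv.P > 0.5) == (lv.y > 0.5)).sum())
        hist.epochs.append({"epoch": epoch, "loss1": tot1 / N, "loss2": tot2 / N,
                            "total": (tot1 + tot2) / N, "train_acc": correct / N})
    return net, hist


def predict_vowel(net: CARSNet, pair) -> tuple[str, float]:
    """Phoneme-level prediction: (label, P_vpi)."""
    p = net.predict_proba(pair.S_n[None], pair.S_o[None])[0]
    return ("vpi" if p[1] > p[0] else "control"), float(p[1])
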