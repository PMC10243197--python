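"""Stage 1: the CGC-BNN tandem mapping descriptors to full UV spectra.

Two Bayesian-regularized networks run in series.  Network A maps the
151-dimensional descriptor vector to the three spectral characteristics
(peak wavelength lambda in nm, area sum S, peak height H).  Network B takes
the descriptors merged with the characteristics (154 inputs) and emits the
58-point normalized UV spectrum.  Network B is trained with the TRUE
characteristics (teacher forcing) and evaluated with network A's predicted
ones; predicted spectra are clipped at zero and not re-normalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ccspec import brnet
from ccspec.molfeat import DESCRIPTOR_LENGTH, DescriptorVector
from ccspec.spectra import (
    GridSpec,
    SpectralCharacteristics,
    Spectrum,
    UV_GRID,
    extract_characteristics,
)

__all__ = ["Stage1Model", "train_stage1", "predict_spectrum",
           "save_stage1", "load_stage1"]

N_CHARACTERISTICS = 3


@dataclass
class Stage1Model:
    """Serial pair of networks: descriptors -> characteristics -> spectrum."""

    net_a: brnet.BayesNetState
    net_b: brnet.BayesNetState
    grid: GridSpec
    seed: int

    def __post_init__(self) -> None:
        in_a = self.net_a.config.layer_sizes[0]
        in_b = self.net_b.config.layer_sizes[0]
        if in_b != in_a + N_CHARACTERISTICS:
            raise ValueError(
                f"net_b input ({in_b}) must be net_a input ({in_a}) + "
                f"{N_CHARACTERISTICS}"
            )


def _as_array(d) -> np.ndarray:
    if isinstance(d, DescriptorVector):
        return d.values
    return np.asarray(d, dtype=float)


def train_stage1(
    records: list[tuple],
    hidden_a: int = 10,
    hidden_b: int = 8,
    max_epochs: int = 40,
    seed: int = 0,
    grid: GridSpec = UV_GRID,
) -> Stage1Model:
    """Fit both networks on (descriptor, normalized spectrum) records.

    Characteristics targets for network A are extracted from the training
    spectra; network B sees the descriptors merged with those true
    characteristics.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 training records")
    X, S = [], []
    for d, s in records:
        arr = _as_array(d)
        if arr.size != DESCRIPTOR_LENGTH:
            raise ValueError(
                f"descriptor length {arr.size} != {DESCRIPTOR_LENGTH}"
            )
        if s.n_points != grid.n:
            raise ValueError(f"spectrum has {s.n_points} points, grid needs {grid.n}")
        X.append(arr)
        S.append(s)
    X = np.stack(X)
    chars = np.stack([extract_characteristics(s).as_array() for s in S])
    Y = np.stack([s.absorbance for s in S])

    cfg_a = brnet.NetConfig(
        layer_sizes=(DESCRIPTOR_LENGTH, hidden_a, N_CHARACTERISTICS),
        max_epochs=max_epochs,
        seed=seed,
    )
    net_a = brnet.train(brnet.init_net(cfg_a), X, chars)

    XB = np.concatenate([X, chars], axis=1)
    cfg_b = brnet.NetConfig(
        layer_sizes=(DESCRIPTOR_LENGTH + N_CHARACTERISTICS, hidden_b, grid.n),
        max_epochs=max_epochs,
        seed=seed + 1,
    )
    net_b = brnet.train(brnet.init_net(cfg_b), XB, Y)
    return Stage1Model(net_a=net_a, net_b=net_b, grid=grid, seed=seed)


def predict_spectrum(m: Stage1Model, d) -> tuple[SpectralCharacteristics, Spectrum]:
    """Predict characteristics then the full spectrum for one descriptor."""
    if not (m.net_a.trained and m.net_b.trained):
        raise ValueError("stage-1 model is not trained")
    x = _as_array(d)
    if x.size != DESCRIPTOR_LENGTH:
        raise ValueError(f"descriptor length {x.size} != {DESCRIPTOR_LENGTH}")
    c = brnet.predict(m.net_a, x[None, :])[0]
    chars = SpectralCharacteristics(float(c[0]), float(c[1]), float(c[2]))
    xb = np.concatenate([x, c])[None, :]
    spec = brnet.predict(m.net_b, xb)[0]
    spectrum = m.grid.spectrum(np.clip(spec, 0.0, None))
    return chars, spectrum


def predict_matrix(m: Stage1Model, X: np.ndarray) -> np.ndarray:
    """Vectorized spectrum prediction for stacked descriptor rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = brnet.predict(m.net_a, X)
    XB = np.concatenate([X, C], axis=1)
    return np.clip(brnet.predict(m.net_b, XB), 0.0, None)


def save_stage1(m: Stage1Model, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    brnet.save_net(m.net_a, outdir / "net_a.json")
    brnet.save_net(m.net_b, outdir / "net_b.json")
    meta = {
        "schema": 1,
        "grid": {"start_nm": m.grid.start_nm, "step_nm": m.grid.step_nm, "n": m.grid.n},
        "seed": m.seed,
    }
    (outdir / "stage1.json").write_text(json.dumps(meta))


def load_stage1(outdir: str | Path) -> Stage1Model:
    outdir = Path(outdir)
    meta = json.loads((outdir / "stage1.json").read_text())
    grid = GridSpec(meta["grid"]["start_nm"], meta["grid"]["step_nm"], meta["grid"]["n"])
    return Stage1Model(
        net_a=brnet.load_net(outdir / "net_a.json"),
        net_b=brnet.load_net(outdir / "net_b.json"),
        grid=grid,
        seed=meta["seed"],
    )
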