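"""Per-channel feature extraction from 26-channel response curves.

Six summaries, each computed independently per sensor channel:

``Ave``
    arithmetic mean of the response over the sampling window.
``Max``
    maximum response value.
``IV``
    integral value — the area under the response curve (trapezoidal rule,
    duration ``(N - 1) / fs`` seconds, units sensor·seconds).
``FFT``
    magnitudes of the first ``fft_n_coeffs`` real-spectrum coefficients
    under 1/N normalisation, so bin 0 is the signal mean and a pure cosine
    of amplitude *a* at bin *k* contributes magnitude *a*/2.
``PCF``
    polynomial curve-fit coefficients (least squares, constant first) on
    the normalised time axis t ∈ [0, 1].
``WT``
    approximation coefficients of a periodized discrete wavelet
    decomposition (default Daubechies-4 at level 7); the periodized form
    of an orthogonal wavelet is an orthonormal transform, so the full
    coefficient set preserves signal energy and reconstructs exactly.

Feature vectors concatenate the per-channel blocks channel-major, columns
named ``<channel>_<method>_<k>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import pywt

from .dataset_io import CHANNEL_IDS, N_CHANNELS, LabeledDataset, SensorArrayRecord

FEATURE_METHODS = ("Ave", "FFT", "IV", "Max", "PCF", "WT")


@dataclass(frozen=True)
class FeatureSpec:
    """One feature method plus its parameters (irrelevant ones are ignored)."""

    method: str
    fft_n_coeffs: int = 8
    poly_degree: int = 5
    wavelet_name: str = "db4"
    wavelet_level: int = 7

    def __post_init__(self) -> None:
        if self.method not in FEATURE_METHODS:
            raise ValueError(
                f"method must be one of {FEATURE_METHODS}, got {self.method!r}"
            )
        if self.fft_n_coeffs < 1:
            raise ValueError(f"fft_n_coeffs must be >= 1, got {self.fft_n_coeffs}")
        if self.poly_degree < 0:
            raise ValueError(f"poly_degree must be >= 0, got {self.poly_degree}")
        if self.wavelet_level < 1:
            raise ValueError(f"wavelet_level must be >= 1, got {self.wavelet_level}")


def default_feature_specs() -> list[FeatureSpec]:
    """The six default specs in canonical (alphabetical) method order."""
    return [FeatureSpec(m) for m in FEATURE_METHODS]


@dataclass
class FeatureVector:
    """Flat feature values for one record with a channel → index-range map."""

    record_id: str
    spec: FeatureSpec
    values: np.ndarray
    block_map: dict[str, tuple[int, int]]


# ---------------------------------------------------------------------------
# Extractors (each returns per-channel blocks, shape block_size × channels)
# ---------------------------------------------------------------------------


def _as_matrix(response: np.ndarray, min_points: int = 1) -> np.ndarray:
    resp = np.asarray(response, dtype=float)
    if resp.ndim != 2 or resp.shape[1] != N_CHANNELS:
        raise ValueError(
            f"response must be a time x {N_CHANNELS} matrix, got shape {resp.shape}"
        )
    if resp.shape[0] < min_points:
        raise ValueError(
            f"response needs >= {min_points} time points, got {resp.shape[0]}"
        )
    return resp


def extract_ave(response: np.ndarray) -> np.ndarray:
    """Per-channel mean of the response over the whole record."""
    return _as_matrix(response).mean(axis=0)


def extract_max(response: np.ndarray) -> np.ndarray:
    """Per-channel maximum of the response over the whole record."""
    return _as_matrix(response).max(axis=0)


def extract_iv(response: np.ndarray, sampling_rate_hz: float) -> np.ndarray:
    """Per-channel area under the response curve (trapezoidal rule).

    The record spans ``(N - 1) / sampling_rate_hz`` seconds; units are
    sensor·seconds.
    """
    resp = _as_matrix(response, min_points=2)
    if sampling_rate_hz <= 0:
        raise ValueError(f"sampling_rate_hz must be > 0, got {sampling_rate_hz}")
    return np.trapezoid(resp, dx=1.0 / sampling_rate_hz, axis=0)


def extract_fft(response: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """First ``fft_n_coeffs`` real-spectrum coefficients per channel.

    1/N normalisation: bin 0 is the (signed) channel mean; bins k ≥ 1 are
    magnitudes scaled so a pure cosine of amplitude *a* at integer bin *k*
    yields *a*/2 there.
    """
    resp = _as_matrix(response)
    n = resp.shape[0]
    n_bins = n // 2 + 1
    if spec.fft_n_coeffs > n_bins:
        raise ValueError(
            f"fft_n_coeffs={spec.fft_n_coeffs} exceeds the {n_bins} nonredundant "
            f"real-spectrum bins of a length-{n} signal"
        )
    spectrum = np.fft.rfft(resp, axis=0)[: spec.fft_n_coeffs] / n
    out = np.abs(spectrum)
    # The DC coefficient of a real signal is real: keep its sign so that
    # bin 0 coincides with the channel mean on any signal.
    out[0] = spectrum[0].real
    return out


def extract_pcf(response: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """Least-squares polynomial coefficients per channel, constant first.

    Fitted on the normalised time axis t ∈ [0, 1] for conditioning.
    """
    resp = _as_matrix(response)
    n = resp.shape[0]
    if spec.poly_degree >= n:
        raise ValueError(
            f"poly_degree={spec.poly_degree} needs more than {n} time points"
        )
    t = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
    coeffs = np.polynomial.polynomial.polyfit(t, resp, spec.poly_degree)
    return np.atleast_2d(coeffs)


def extract_wt(response: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """Level-L approximation coefficients of a discrete wavelet decomposition."""
    resp = _as_matrix(response)
    n = resp.shape[0]
    wavelet = pywt.Wavelet(spec.wavelet_name)
    max_level = pywt.dwt_max_level(n, wavelet.dec_len)
    if spec.wavelet_level > max_level:
        raise ValueError(
            f"wavelet_level={spec.wavelet_level} infeasible for {n} time points "
            f"with {spec.wavelet_name}: maximum level is {max_level}"
        )
    coeffs = pywt.wavedec(
        resp, wavelet, level=spec.wavelet_level, axis=0, mode="periodization"
    )
    return coeffs[0]


def block_size(spec: FeatureSpec, n_points: int) -> int:
    """Per-channel feature count for ``spec`` on records of ``n_points``."""
    if spec.method in ("Ave", "IV", "Max"):
        return 1
    if spec.method == "FFT":
        return spec.fft_n_coeffs
    if spec.method == "PCF":
        return spec.poly_degree + 1
    wavelet = pywt.Wavelet(spec.wavelet_name)
    length = n_points
    for _ in range(spec.wavelet_level):
        length = pywt.dwt_coeff_len(length, wavelet.dec_len, "periodization")
    return length


def feature_names(spec: FeatureSpec, n_points: int) -> list[str]:
    size = block_size(spec, n_points)
    return [
        f"{ch}_{spec.method}_{k}" for ch in CHANNEL_IDS for k in range(size)
    ]


def _extract_block(
    response: np.ndarray, spec: FeatureSpec, sampling_rate_hz: float
) -> np.ndarray:
    if spec.method == "Ave":
        return extract_ave(response)[None, :]
    if spec.method == "Max":
        return extract_max(response)[None, :]
    if spec.method == "IV":
        return extract_iv(response, sampling_rate_hz)[None, :]
    if spec.method == "FFT":
        return extract_fft(response, spec)
    if spec.method == "PCF":
        return extract_pcf(response, spec)
    return extract_wt(response, spec)


def featurize_record(
    record: SensorArrayRecord,
    spec: FeatureSpec,
    subtract_baseline: bool = False,
) -> FeatureVector:
    """Compute one record's flat feature vector (channel-major blocks)."""
    response = np.asarray(record.response, dtype=float)
    if subtract_baseline:
        response = response - response[0]
    block = _extract_block(response, spec, record.sampling_rate_hz)
    size = block.shape[0]
    values = block.T.reshape(-1)  # channel-major
    if not np.all(np.isfinite(values)):
        raise ValueError(
            f"non-finite feature values for record {record.record_id} "
            f"({spec.method})"
        )
    block_map = {
        ch: (c * size, (c + 1) * size) for c, ch in enumerate(CHANNEL_IDS)
    }
    return FeatureVector(record.record_id, spec, values, block_map)


LABEL_COLUMNS = ("record_id", "class_id", "condition")


def featurize_dataset(
    dataset: LabeledDataset,
    spec: FeatureSpec,
    subtract_baseline: bool = False,
) -> pd.DataFrame:
    """Feature table for a whole dataset: label columns then feature columns.

    All records must share the same time-point count and sampling rate; row
    order follows dataset order.
    """
    if len(dataset) == 0:
        return pd.DataFrame(columns=list(LABEL_COLUMNS))
    first = dataset.records[0]
    shape = (first.n_points, first.response.shape[1])
    rate = first.sampling_rate_hz
    for rec in dataset:
        if rec.response.shape != shape or rec.sampling_rate_hz != rate:
            raise ValueError(
                f"record {rec.record_id} has shape {rec.response.shape} @ "
                f"{rec.sampling_rate_hz} Hz, expected {shape} @ {rate} Hz"
            )
    names = feature_names(spec, first.n_points)
    values = np.empty((len(dataset), len(names)))
    for i, rec in enumerate(dataset):
        values[i] = featurize_record(rec, spec, subtract_baseline).values
    table = pd.DataFrame(values, columns=names)
    table.insert(0, "condition", dataset.conditions)
    table.insert(0, "class_id", dataset.class_ids)
    table.insert(0, "record_id", dataset.record_ids)
    return table


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """Numeric feature block of a feature table (labels stripped)."""
    cols = [c for c in table.columns if c not in LABEL_COLUMNS]
    return table[cols].to_numpy(dtype=float)
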