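"""Virtual EEG: lead-field projection of simulated sources and spectra.

Simulated pyramidal potentials are converted to sensor space by multiplying
with the reciprocity-derived lead field; spectral summaries (Welch PSD,
spectrogram, band power per channel) support comparison of baseline and
stimulated runs.  Voltages are in arbitrary units unless a physical dipole
scaling is supplied — the spatial pattern and spectral content, not the
absolute magnitude, are the modeled quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .em import LeadFieldMatrix
from .jansen_rit import SimOutput

__all__ = ["EEGRecord", "SpectralResult", "project_eeg", "psd", "spectrogram",
           "band_topography"]


@dataclass
class EEGRecord:
    """Channels x time voltage matrix with 10-10 labels."""

    labels: list[str]
    fs: float
    data: np.ndarray           # (n_channels, n_samples)
    reference: str             # "average" or an electrode label
    meta: dict = field(default_factory=dict)


@dataclass
class SpectralResult:
    frequencies: np.ndarray
    psd: np.ndarray                     # (n_channels, n_freqs)
    labels: list[str]
    times: np.ndarray | None = None     # spectrogram segment centers
    spectrogram: np.ndarray | None = None   # (n_channels, n_freqs, n_times)
    band_power: np.ndarray | None = None
    band_Hz: tuple[float, float] | None = None

    @property
    def mean_psd(self) -> np.ndarray:
        return self.psd.mean(axis=0)

    def peak_frequency(self, fmin: float = 1.0, channel_average: bool = True) -> float:
        """Frequency of the PSD global maximum above ``fmin``."""
        sel = self.frequencies > fmin
        p = self.mean_psd if channel_average else self.psd.max(axis=0)
        return float(self.frequencies[sel][np.argmax(p[sel])])


def project_eeg(sim: SimOutput, lf: LeadFieldMatrix, source_scale: float = 1.0,
                region_of_vertex: np.ndarray | None = None,
                reference: str = "average") -> EEGRecord:
    """Sensor-space voltages ``V(t) = LF @ (source_scale * v_pyr(t))``.

    The lead field columns are mesh vertices; for a region-mode simulation
    pass ``region_of_vertex`` to broadcast each region's trace to its member
    vertices.  The record is re-referenced afterwards (default: average
    reference, zero channel mean per sample).
    """
    src = source_scale * sim.v_pyr
    if region_of_vertex is not None:
        src = src[region_of_vertex]          # (n_vertices, T)
    if lf.matrix.shape[1] != src.shape[0]:
        raise ValueError(
            f"lead field has {lf.matrix.shape[1]} source columns but the "
            f"simulation provides {src.shape[0]} sources")
    v = lf.matrix @ src
    if reference == "average":
        v = v - v.mean(axis=0, keepdims=True)
    else:
        v = v - v[lf.labels.index(reference)]
    return EEGRecord(labels=list(lf.labels), fs=sim.fs, data=v, reference=reference,
                     meta={"source_scale": source_scale, "seed": sim.seed})


def psd(rec: EEGRecord, window_s: float = 2.0, overlap: float = 0.5) -> SpectralResult:
    """Per-channel Welch PSD (Hann windows, default 2 s at 50% overlap)."""
    nper = int(round(window_s * rec.fs))
    f, p = signal.welch(rec.data, fs=rec.fs, nperseg=nper,
                        noverlap=int(nper * overlap), axis=1)
    return SpectralResult(frequencies=f, psd=p, labels=list(rec.labels))


def spectrogram(rec: EEGRecord, window_s: float = 2.0, step_s: float = 0.5) -> SpectralResult:
    """Short-time PSD per channel: (channels, freqs, times)."""
    nper = int(round(window_s * rec.fs))
    nover = nper - int(round(step_s * rec.fs))
    f, t, s = signal.spectrogram(rec.data, fs=rec.fs, nperseg=nper,
                                 noverlap=max(nover, 0), axis=1)
    return SpectralResult(frequencies=f, psd=s.mean(axis=-1), labels=list(rec.labels),
                          times=t, spectrogram=s)


def band_topography(rec: EEGRecord, band_Hz: tuple[float, float] = (8.0, 12.0),
                    window_s: float = 2.0, overlap: float = 0.5) -> SpectralResult:
    """Band-integrated PSD per channel (for topographic map rendering)."""
    res = psd(rec, window_s=window_s, overlap=overlap)
    lo, hi = band_Hz
    sel = (res.frequencies >= lo) & (res.frequencies <= hi)
    bp = np.trapezoid(res.psd[:, sel], res.frequencies[sel], axis=1)
    res.band_power = bp
    res.band_Hz = (float(lo), float(hi))
    return res
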