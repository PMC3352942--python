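"""Band filtering, spectral power and lead substitution.

The filtering convention follows common resting-EEG practice: a windowed-sinc
FIR band-pass applied forward and backward (zero phase), with the -6 dB points
of the magnitude response at the nominal band edges. Band power uses Welch's
method on 50%-overlapping segments and integrates the density over the band,
so a pure in-band sinusoid of amplitude A yields a band power of A**2 / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import ChannelError, ConfigurationError, LengthError, Recording


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ConfigurationError(
                f"band {self.name}: need 0 < low < high, got ({self.low}, {self.high})"
            )

    def validate_against(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ConfigurationError(
                f"band {self.name} upper edge {self.high} Hz >= Nyquist {fs / 2} Hz"
            )


#: Default band definitions used throughout the pipeline.
DEFAULT_BANDS = {
    "theta": BandDefinition("theta", 3.0, 5.6),
    "alpha": BandDefinition("alpha", 6.0, 13.0),
    "beta": BandDefinition("beta", 15.0, 25.0),
    "broadband": BandDefinition("broadband", 1.0, 37.0),
}


def _fir_taps(band: BandDefinition, fs: float) -> np.ndarray:
    # Transition width scales with the lower edge but is capped so narrow
    # bands stay realizable on 12-s epochs; firwin (Hamming) puts the -6 dB
    # point at each cutoff, matching the stated roll-off convention.
    transition = float(np.clip(0.25 * band.low, 0.5, 2.0))
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # odd length -> type I linear phase
    return signal.firwin(numtaps, [band.low, band.high], pass_zero=False, fs=fs)


def fir_bandpass(rec: Recording, band: BandDefinition) -> Recording:
    """Zero-phase FIR band-pass of every channel.

    The filter is applied forward-backward (``filtfilt``) so in-band
    components suffer no group delay; stop-band attenuation is therefore
    doubled (in dB) relative to a single pass.
    """
    band.validate_against(rec.fs)
    taps = _fir_taps(band, rec.fs)
    if rec.n_samples <= 3 * len(taps):
        raise LengthError(
            f"recording of {rec.n_samples} samples too short for "
            f"{len(taps)}-tap zero-phase filter (need > {3 * len(taps)})"
        )
    out = signal.filtfilt(taps, [1.0], rec.data, axis=1)
    meta = dict(rec.meta)
    meta["filter"] = {"band": band.name, "low": band.low, "high": band.high,
                      "numtaps": len(taps), "design": "firwin-hamming/filtfilt"}
    return rec.copy_with(data=out, meta=meta)


def welch_band_power(
    rec: Recording,
    band: BandDefinition,
    nperseg: int = 4096,
    overlap: float = 0.5,
) -> np.ndarray:
    """Band-integrated Welch power per channel (signal units squared).

    Density is estimated on ``overlap``-overlapping stretches of ``nperseg``
    samples and summed over the frequency bins inside [low, high], scaled by
    the bin width, so the result approximates the in-band signal variance.
    """
    band.validate_against(rec.fs)
    if rec.n_samples < nperseg:
        raise LengthError(
            f"recording of {rec.n_samples} samples shorter than nperseg={nperseg}; "
            "reduce nperseg or supply a longer recording"
        )
    freqs, psd = signal.welch(
        rec.data, fs=rec.fs, nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), axis=1,
    )
    mask = (freqs >= band.low) & (freqs <= band.high)
    df = freqs[1] - freqs[0]
    return psd[:, mask].sum(axis=1) * df


def substitute_leads(rec: Recording, mapping: dict[str, str]) -> Recording:
    """Relabel channels per ``mapping`` (source label -> target label).

    The data are untouched; the renamed channels are flagged as substituted so
    downstream scoring can apply the paired-bias correction. Mapping onto a
    label that already exists (and is not itself being renamed away) is an
    error.
    """
    if not mapping:
        return rec
    for src in mapping:
        if src not in rec.labels:
            raise ChannelError(f"source label {src!r} not present")
    remaining = set(rec.labels) - set(mapping)
    targets = list(mapping.values())
    if len(set(targets)) != len(targets):
        raise ChannelError("duplicate target labels in mapping")
    for tgt in targets:
        if tgt in remaining:
            raise ChannelError(f"target label {tgt!r} collides with existing channel")
    labels = [mapping.get(lab, lab) for lab in rec.labels]
    flags = rec.substituted | frozenset(mapping.values())
    return rec.copy_with(labels=labels, substituted=flags)
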