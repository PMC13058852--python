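"""Acquisition-timing arithmetic for ultrafast compound imaging.

Plane-wave fUSI transmits tilted plane waves at a pulse repetition frequency
(PRF); one beamformed compound frame is produced per full angle sweep, and one
power Doppler volume per fixed-length block of compound frames (optionally
separated by an inter-block delay).
"""

from __future__ import annotations

from .errors import ParameterError


def compound_frame_rate(prf_hz: float, n_angles: int) -> float:
    """Compound (I/Q) frame rate after angle compounding.

    Parameters
    ----------
    prf_hz
        Pulse repetition frequency of individual plane-wave transmits, Hz.
    n_angles
        Number of tilted plane waves compounded into one frame.
    """
    if prf_hz <= 0:
        raise ParameterError("prf_hz must be positive")
    if n_angles < 1:
        raise ParameterError("n_angles must be >= 1")
    return prf_hz / n_angles


def power_doppler_rate(
    f_iq_hz: float, block_len: int, inter_block_delay_s: float = 0.0
) -> float:
    """Power Doppler volume rate from block length and optional dead time.

    A block of ``block_len`` compound frames at ``f_iq_hz`` spans
    ``block_len / f_iq_hz`` seconds; an acquisition may insert a delay after
    each block (e.g. 100 ms), lowering the volume rate accordingly.
    """
    if f_iq_hz <= 0:
        raise ParameterError("f_iq_hz must be positive")
    if block_len < 1:
        raise ParameterError("block_len must be >= 1")
    if inter_block_delay_s < 0:
        raise ParameterError("inter_block_delay_s must be >= 0")
    return 1.0 / (block_len / f_iq_hz + inter_block_delay_s)
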