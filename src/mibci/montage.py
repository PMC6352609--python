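"""The 32-channel 10-20 montage used throughout the package.

Channels cover the fronto-central, central, centro-parietal, parietal,
parieto-occipital and occipital rows — the sites where mu/beta
sensorimotor rhythms and their imagery-induced modulation are visible.
An auxiliary EMG channel is appended by the simulator to mirror the
acquisition setup (it carries no EEG and is excluded from analysis).

The spatial gain map (how strongly each channel expresses the
contralateral ERD effect for a right-hand task) is shipped as a static
JSON data file; it is a Gaussian fall-off centred on C3 over approximate
2-D montage coordinates, giving a reproducible contralateral topography
without head modelling.
"""

from __future__ import annotations

import json
from importlib import resources

EEG_CHANNELS: tuple[str, ...] = (
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P3", "P1", "Pz", "P2", "P4",
    "PO3", "POz", "PO4",
    "O1", "Oz", "O2",
)

EMG_CHANNEL = "EMG"

DEFAULT_CHANNELS: tuple[str, ...] = EEG_CHANNELS + (EMG_CHANNEL,)


def load_spatial_gains() -> dict[str, float]:
    """Per-channel weight in [0, 1] of the contralateral (right-hand) ERD effect.

    Loaded from the packaged ``data/spatial_gains.json``; C3 has weight 1,
    weights decay with distance from C3 and are ~0 over the ipsilateral
    and occipital sites. The EMG channel always has weight 0.
    """
    with resources.files("mibci").joinpath("data/spatial_gains.json").open() as fh:
        gains = json.load(fh)
    gains[EMG_CHANNEL] = 0.0
    return gains
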