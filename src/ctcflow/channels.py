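"""The fixed five-channel panel.

Channel order is part of the data contract: event tables, spillover matrices
and gate specs all index channels by these names, in this order.

========  ===========  =============================================
channel   fluorophore  stains
========  ===========  =============================================
hoechst   Hoechst      nuclei (DNA)
ck        FITC         cytokeratin 7/8/18/19 (epithelial marker)
vim       PE           vimentin (mesenchymal marker)
cd45      PE-Cy7       CD45 (leukocyte lineage marker)
her2      AF647        HER2 / erbB2 membrane receptor
========  ===========  =============================================
"""

from __future__ import annotations

CHANNELS: tuple[str, ...] = ("hoechst", "ck", "vim", "cd45", "her2")

N_CHANNELS = len(CHANNELS)

CHANNEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(CHANNELS)}


def validate_channel(name: str) -> str:
    from ctcflow.errors import ValidationError

    if name not in CHANNEL_INDEX:
        raise ValidationError(
            f"unknown channel {name!r}; expected one of {CHANNELS}"
        )
    return name
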