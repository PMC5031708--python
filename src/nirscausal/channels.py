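"""Channel registry for the 46-channel frontal + occipital fNIRS montage.

The montage is the two-probe-set ETG-4000 layout used in developmental
own-/other-race face studies: a pair of 3x3 arrays over the forehead forming
channels 1-24 (frontal block) and a 3x5 array over the back of the head
forming channels 25-46 (occipital block).  Each channel carries its estimated
MNI coordinate, a Brodmann-area number, and an AAL anatomical label.

Region membership is defined by the probe-set blocks (ids 1-24 frontal,
25-46 occipital), not by parsing the anatomical labels: a handful of
frontal-set channels land on labels such as PreCG that are not literally
frontal gyri, but they belong to the frontal probe set.  Hemisphere comes
from the AAL label prefix and is cross-checked against the sign of the MNI
x coordinate; a mismatch is only warned about, since near-midline channels
can straddle x = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import RegistryError, SelfLoopError

N_FRONTAL = 24
N_OCCIPITAL = 22
N_CHANNELS = N_FRONTAL + N_OCCIPITAL

_DEFAULT_TABLE = "etg4000_46ch_montage.tsv"


class Region(str, Enum):
    frontal = "frontal"
    occipital = "occipital"


class Hemisphere(str, Enum):
    L = "L"
    R = "R"


class EdgeClass(str, Enum):
    """Class of an ordered channel pair by probe-set membership."""

    intra_frontal = "intra_frontal"
    intra_occipital = "intra_occipital"
    inter_frontal_to_occipital = "inter_frontal_to_occipital"
    inter_occipital_to_frontal = "inter_occipital_to_frontal"


@dataclass(frozen=True)
class ChannelInfo:
    """One montage channel.

    Attributes
    ----------
    id : int
        Channel number, 1..46.
    mni : tuple of float
        (x, y, z) MNI coordinate in millimetres.
    ba : int
        Brodmann area.
    aal : str
        AAL label, e.g. ``"L IFGtriang"``.
    region : Region
        Probe-set block (frontal for ids 1-24, occipital for 25-46).
    hemisphere : Hemisphere
        Left/right, from the AAL label prefix.
    """

    id: int
    mni: tuple[float, float, float]
    ba: int
    aal: str
    region: Region
    hemisphere: Hemisphere


def region_of(channel_id: int) -> Region:
    """Region of a channel id under the probe-set block rule."""
    if not 1 <= int(channel_id) <= N_CHANNELS:
        raise RegistryError(f"channel id {channel_id} out of range 1..{N_CHANNELS}")
    return Region.frontal if channel_id <= N_FRONTAL else Region.occipital


def classify_edge(from_ch: int, to_ch: int) -> EdgeClass:
    """Classify a directed edge by the regions of its endpoints.

    Raises
    ------
    SelfLoopError
        If ``from_ch == to_ch``.
    RegistryError
        If either id is outside 1..46.
    """
    if int(from_ch) == int(to_ch):
        raise SelfLoopError(f"self-loop {from_ch}->{to_ch} has no edge class")
    src, dst = region_of(from_ch), region_of(to_ch)
    if src is Region.frontal and dst is Region.frontal:
        return EdgeClass.intra_frontal
    if src is Region.occipital and dst is Region.occipital:
        return EdgeClass.intra_occipital
    if src is Region.frontal:
        return EdgeClass.inter_frontal_to_occipital
    return EdgeClass.inter_occipital_to_frontal


def _row_to_channel(row: pd.Series) -> ChannelInfo:
    cid = int(row["id"])
    try:
        mni = (float(row["x"]), float(row["y"]), float(row["z"]))
    except (TypeError, ValueError) as exc:
        raise RegistryError(f"malformed MNI coordinate for channel {cid}: {exc}") from exc
    aal = str(row["aal"]).strip()
    prefix = aal.split()[0] if aal.split() else ""
    if prefix not in ("L", "R"):
        raise RegistryError(f"channel {cid}: AAL label {aal!r} lacks an L/R prefix")
    hemi = Hemisphere(prefix)
    x = mni[0]
    if (hemi is Hemisphere.L and x >= 0) or (hemi is Hemisphere.R and x < 0):
        warnings.warn(
            f"channel {cid}: hemisphere {hemi.value} disagrees with MNI x={x:g} "
            "(near-midline channel?)",
            stacklevel=3,
        )
    return ChannelInfo(
        id=cid,
        mni=mni,
        ba=int(row["ba"]),
        aal=aal,
        region=region_of(cid),
        hemisphere=hemi,
    )


def load_channel_table(path: str | Path | None = None) -> tuple[ChannelInfo, ...]:
    """Load a channel registry from a tab-separated table.

    The table needs columns ``id, x, y, z, ba, aal`` and must contain exactly
    one row for every channel 1..46.  With ``path=None`` the packaged default
    montage is loaded.
    """
    if path is None:
        with resources.files("nirscausal.data").joinpath(_DEFAULT_TABLE).open("r") as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    missing = {"id", "x", "y", "z", "ba", "aal"} - set(df.columns)
    if missing:
        raise RegistryError(f"channel table lacks columns: {sorted(missing)}")
    ids = df["id"].astype(int).tolist()
    if len(ids) != len(set(ids)):
        raise RegistryError("duplicate channel ids in registry")
    if sorted(ids) != list(range(1, N_CHANNELS + 1)):
        raise RegistryError(
            f"registry must cover exactly ids 1..{N_CHANNELS}; got {len(ids)} rows"
        )
    channels = tuple(
        _row_to_channel(row) for _, row in df.sort_values("id").iterrows()
    )
    return channels


def write_channel_table(channels: Iterable[ChannelInfo], path: str | Path) -> None:
    """Write a registry back to the tab-separated interchange format."""
    rows = [
        {
            "id": c.id,
            "x": c.mni[0],
            "y": c.mni[1],
            "z": c.mni[2],
            "ba": c.ba,
            "aal": c.aal,
        }
        for c in sorted(channels, key=lambda c: c.id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_default_cache: tuple[ChannelInfo, ...] | None = None


def default_channels() -> tuple[ChannelInfo, ...]:
    """The packaged 46-channel montage (cached)."""
    global _default_cache
    if _default_cache is None:
        _default_cache = load_channel_table(None)
    return _default_cache


def edge_class_counts(channels: Sequence[ChannelInfo] | None = None) -> dict[EdgeClass, int]:
    """Counts of all ordered distinct channel pairs per edge class."""
    n = len(channels) if channels is not None else N_CHANNELS
    counts = {k: 0 for k in EdgeClass}
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if i != j:
                counts[classify_edge(i, j)] += 1
    return counts
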