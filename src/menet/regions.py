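"""Channel-to-region maps for the four-region scalp partition."""

from __future__ import annotations

from pathlib import Path

from .errors import ConfigurationError
from .simulate import REGION_NAMES, make_region_map

__all__ = ["load_region_map", "save_region_map", "validate_region_map",
           "default_region_map", "biosemi128_region_map"]


def validate_region_map(region_map: dict[str, str]) -> dict[str, str]:
    """Check total cover of the four regions, rejecting unknown region names."""
    if not region_map:
        raise ConfigurationError("RegionMap is empty")
    bad = {ch: r for ch, r in region_map.items() if r not in REGION_NAMES}
    if bad:
        raise ConfigurationError(f"RegionMap has unknown regions: {bad}")
    present = set(region_map.values())
    missing = [r for r in REGION_NAMES if r not in present]
    if missing:
        raise ConfigurationError(f"RegionMap leaves regions empty: {missing}")
    return region_map


def load_region_map(path: str | Path) -> dict[str, str]:
    """Read a channel,region CSV; duplicate channels are configuration errors."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"RegionMap file not found: {path}")
    region_map: dict[str, str] = {}
    dupes = []
    with open(path) as fh:
        header = next(fh)
        if "channel" not in header:
            raise ConfigurationError("RegionMap CSV must have a 'channel,region' header")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            ch, region = [s.strip() for s in line.split(",")[:2]]
            if ch in region_map:
                dupes.append(ch)
            region_map[ch] = region
    if dupes:
        raise ConfigurationError(f"RegionMap assigns channels twice: {sorted(set(dupes))}")
    return validate_region_map(region_map)


def save_region_map(region_map: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("channel,region\n")
        for ch, region in region_map.items():
            fh.write(f"{ch},{region}\n")
    return path


def biosemi128_region_map() -> dict[str, str]:
    """Coarse four-region partition of the BioSemi 128-channel ABCD montage.

    Ring-level approximation of the standard scalp geometry: the C ring
    (fronto-central) -> frontal, A ring (centro-parietal) -> parietal, B ring
    (posterior) -> occipital, D ring (left fronto-temporal) -> temporal.  It
    is deliberately coarse -- electrode-exact assignments depend on the lab's
    montage -- and intended to be overridden with a lab-specific CSV.
    """
    out: dict[str, str] = {}
    ring_to_region = {"A": "parietal", "B": "occipital", "C": "frontal", "D": "temporal"}
    for ring, region in ring_to_region.items():
        for k in range(1, 33):
            out[f"{ring}{k}"] = region
    return out


def default_region_map(channel_ids: tuple[str, ...]) -> dict[str, str]:
    """Best default for a channel set: BioSemi ABCD names if they match, else
    contiguous near-equal blocks in channel order."""
    biosemi = biosemi128_region_map()
    if set(channel_ids) <= set(biosemi):
        return {ch: biosemi[ch] for ch in channel_ids}
    return make_region_map(tuple(channel_ids))
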