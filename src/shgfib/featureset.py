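"""Registry of the 100 named collagen features.

The feature vector is organised as three 28-feature region blocks (central
vein ``CV``, portal tract ``PT``, perisinusoidal ``PS``) followed by a
16-feature whole-tissue block.  Each region block contains

* 4 percentages: the region's collagen as a share of total tissue area
  (named after the region itself, e.g. ``CV``), the collagen share of the
  region's own area (``ColCV``) and its split into aggregated (cross-linked)
  and distributed collagen (``AggCV``, ``DisCV``);
* 15 string counts per mm² of region area: total / short / long / thick /
  thin strings, each for all strings and for the aggregated (``A``) and
  distributed (``D``) subsets;
* 9 string statistics: mean string area (μm²), skeleton length (μm) and
  width (μm), again for all / aggregated / distributed strings.

The global block repeats the percentages, the five counts, the A/D count
split and the three mean statistics for all and aggregated strings over the
entire tissue.  Fourteen of these features form the selected set used by the
linear fibrosis index (:mod:`shgfib.staging`).
"""

from __future__ import annotations

REGIONS = ("CV", "PT", "PS")

_COUNT_BASES = ("NoStr", "NoShortStr", "NoLongStr", "NoThickStr", "NoThinStr")
_STAT_BASES = ("StrArea", "StrLength", "StrWidth")


def _region_block(region: str) -> list[str]:
    names = [region, f"Col{region}", f"Agg{region}", f"Dis{region}"]
    for suffix in ("", "A", "D"):
        names += [f"{base}{region}{suffix}" for base in _COUNT_BASES]
    for suffix in ("", "A", "D"):
        names += [f"{base}{region}{suffix}" for base in _STAT_BASES]
    return names


def _global_block() -> list[str]:
    names = ["Col", "Agg", "Dis"]
    names += list(_COUNT_BASES)
    names += ["NoStrA", "NoStrD"]
    names += list(_STAT_BASES)
    names += [f"{base}A" for base in _STAT_BASES]
    return names


#: All 100 feature names: CV block, PT block, PS block, global block.
FEATURE_NAMES: tuple[str, ...] = tuple(
    name for region in REGIONS for name in _region_block(region)
) + tuple(_global_block())

REGION_BLOCKS: dict[str, tuple[str, ...]] = {
    region: tuple(_region_block(region)) for region in REGIONS
}
GLOBAL_BLOCK: tuple[str, ...] = tuple(_global_block())

#: Alternative spellings accepted on input.  ``StrLengthSFD`` is the
#: historical name of the PS-distributed string length.
FEATURE_ALIASES: dict[str, str] = {"StrLengthSFD": "StrLengthPSD"}

#: The 14 features retained by sequential forward selection for the fibrosis
#: index, in their conventional order.
SELECTED_FEATURES: tuple[str, ...] = (
    "Agg",
    "StrWidth",
    "CV",
    "NoThickStrCV",
    "StrAreaCV",
    "StrLengthCV",
    "StrLengthCVA",
    "StrAreaCVD",
    "NoThinStrPTA",
    "NoThickStrPTD",
    "NoStrPSD",
    "NoShortStrPSD",
    "StrAreaPSD",
    "StrLengthPSD",
)


def resolve_feature_name(name: str) -> str:
    """Map a (possibly aliased) feature name to its canonical registry name."""
    canonical = FEATURE_ALIASES.get(name, name)
    if canonical not in FEATURE_NAMES:
        raise KeyError(f"unknown collagen feature: {name!r}")
    return canonical


def feature_schema() -> dict:
    """JSON-serialisable description of the feature registry."""
    return {
        "n_features": len(FEATURE_NAMES),
        "regions": list(REGIONS),
        "region_blocks": {r: list(b) for r, b in REGION_BLOCKS.items()},
        "global_block": list(GLOBAL_BLOCK),
        "selected": list(SELECTED_FEATURES),
        "aliases": dict(FEATURE_ALIASES),
    }


assert len(FEATURE_NAMES) == 100
assert all(len(b) == 28 for b in REGION_BLOCKS.values())
assert len(GLOBAL_BLOCK) == 16
assert len(set(FEATURE_NAMES)) == 100
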