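"""Minimal Praat TextGrid (long text format) writing and reading.

Supports interval tiers (utterance spans) and point tiers (MTP times/f0,
INTSINT labels) — enough to inspect pipeline output in Praat.
"""

from __future__ import annotations

import re
from dataclasses import dataclass


@dataclass
class PointTier:
    name: str
    points: list[tuple[float, str]]  # (time_s, mark)


@dataclass
class IntervalTier:
    name: str
    intervals: list[tuple[float, float, str]]  # (start_s, end_s, text)


def write_textgrid(path: str, xmin: float, xmax: float,
                   tiers: list[PointTier | IntervalTier]) -> None:
    lines = ['File type = "ooTextFile"', 'Object class = "TextGrid"', "",
             f"xmin = {xmin:.6f}", f"xmax = {xmax:.6f}",
             "tiers? <exists>", f"size = {len(tiers)}", "item []:"]
    for i, tier in enumerate(tiers, 1):
        lines.append(f"    item [{i}]:")
        if isinstance(tier, PointTier):
            lines += [f'        class = "TextTier"',
                      f'        name = "{tier.name}"',
                      f"        xmin = {xmin:.6f}", f"        xmax = {xmax:.6f}",
                      f"        points: size = {len(tier.points)}"]
            for j, (t, mark) in enumerate(tier.points, 1):
                lines += [f"        points [{j}]:",
                          f"            number = {t:.6f}",
                          f'            mark = "{mark}"']
        else:
            lines += [f'        class = "IntervalTier"',
                      f'        name = "{tier.name}"',
                      f"        xmin = {xmin:.6f}", f"        xmax = {xmax:.6f}",
                      f"        intervals: size = {len(tier.intervals)}"]
            for j, (a, b, text) in enumerate(tier.intervals, 1):
                lines += [f"        intervals [{j}]:",
                          f"            xmin = {a:.6f}",
                          f"            xmax = {b:.6f}",
                          f'            text = "{text}"']
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_textgrid(path: str) -> list[PointTier | IntervalTier]:
    """Parse a long-format TextGrid back into tier objects."""
    with open(path) as fh:
        text = fh.read()
    if '"TextGrid"' not in text:
        raise ValueError(f"{path!r} is not a TextGrid file")
    tiers: list[PointTier | IntervalTier] = []
    chunks = re.split(r"item \[\d+\]:", text)[1:]
    for chunk in chunks:
        cls = re.search(r'class = "(\w+)"', chunk).group(1)
        name = re.search(r'name = "([^"]*)"', chunk).group(1)
        if cls == "TextTier":
            pts = [(float(m.group(1)), m.group(2)) for m in re.finditer(
                r'number = ([\d.eE+-]+)\s*\n\s*mark = "([^"]*)"', chunk)]
            tiers.append(PointTier(name, pts))
        else:
            ivs = [(float(m.group(1)), float(m.group(2)), m.group(3))
                   for m in re.finditer(
                r'xmin = ([\d.eE+-]+)\s*\n\s*xmax = ([\d.eE+-]+)\s*\n'
                r'\s*text = "([^"]*)"', chunk)]
            tiers.append(IntervalTier(name, ivs))
    return tiers
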