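"""Study-design builders: questionnaire items and comparison grids."""

from __future__ import annotations

from itertools import product

from .agreement import descriptor_catalog


def build_questionnaire(image_ids, descriptors: list[str] | None = None) -> list[dict]:
    """One 5-point Likert item per (image, descriptor).

    For the emulated study design (15 drawn + 15 geometric images against
    the 13-descriptor catalog) this yields 390 items.
    """
    descriptors = descriptors if descriptors is not None else descriptor_catalog()
    return [
        {"image_id": img, "descriptor_index": d, "statement": text}
        for img in image_ids
        for d, text in enumerate(descriptors)
    ]


def comparison_grid(items, full_grid: bool = True) -> list[tuple]:
    """Pairwise comparison cells for one similarity block.

    ``full_grid=True`` counts every ordered pairing including self-pairings
    (n^2 cells — 225 for a 15-image block); otherwise unordered pairs
    including self-pairings (n(n+1)/2).
    """
    items = list(items)
    if full_grid:
        return list(product(items, items))
    return [(a, b) for i, a in enumerate(items) for b in items[i:]]
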