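"""Region label registry.

Label conventions are fixed here so every module agrees on column names:
amygdala subnuclei are ``am_{L|R}_{nucleus}`` using the FreeSurfer
subsegmentation nucleus names, brain regions are ``brain_###``.
"""

from __future__ import annotations

AMYGDALA_NUCLEI: tuple[str, ...] = (
    "lateral",
    "basal",
    "accessory_basal",
    "paralaminar",
    "central",
    "medial",
    "cortical",
    "anterior_amygdaloid_area",
    "corticoamygdaloid_transition",
)


def amygdala_labels(n_amygdala: int = 18) -> list[str]:
    """Mirrored left/right amygdala labels: left half first, then right.

    ``n_amygdala`` must be even; each half reuses the nucleus registry,
    cycling with a numeric suffix if more than 9 per hemisphere are asked for.
    """
    if n_amygdala % 2 != 0:
        raise ValueError(f"n_amygdala must be even, got {n_amygdala}")
    half = n_amygdala // 2
    names = []
    for i in range(half):
        base = AMYGDALA_NUCLEI[i % len(AMYGDALA_NUCLEI)]
        suffix = "" if i < len(AMYGDALA_NUCLEI) else f"_{i // len(AMYGDALA_NUCLEI) + 1}"
        names.append(base + suffix)
    return [f"am_L_{n}" for n in names] + [f"am_R_{n}" for n in names]


def brain_labels(n_brain: int = 109) -> list[str]:
    return [f"brain_{i:03d}" for i in range(1, n_brain + 1)]


def split_hemispheres(labels: list[str]) -> tuple[list[str], list[str]]:
    """Partition amygdala labels into (left, right), preserving order."""
    left = [l for l in labels if l.startswith("am_L_")]
    right = [l for l in labels if l.startswith("am_R_")]
    if len(left) != len(right):
        raise ValueError(
            f"hemisphere halves differ in size: {len(left)} left vs {len(right)} right"
        )
    mirrored = [l.replace("am_L_", "am_R_", 1) for l in left]
    if mirrored != right:
        raise ValueError("left/right amygdala labels are not mirrored")
    return left, right
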