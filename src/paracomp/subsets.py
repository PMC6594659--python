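"""Set machinery over differential-expression gene lists.

UpSet-style membership-pattern enumeration over named gene lists, and
the temporal classification of stage-wise DE lists filtered against a
reference-enriched gene set (e.g. FACS-sorted neural crest genes):
genes changing only early, only mid, only late, persistently, and the
transitional classes in between.
"""

from __future__ import annotations

from typing import Iterable, Mapping

#: Temporal class names in developmental order.
TEMPORAL_CLASSES = (
    "early",
    "early-mid",
    "mid",
    "mid-later",
    "later",
    "persistent",
    "discontinuous",
)


def membership_patterns(
    collection: Mapping[str, Iterable[str]],
) -> dict[tuple[int, ...], set[str]]:
    """Partition the union of named gene lists by membership pattern.

    The key is a bit tuple over the collection's names in their given
    order (1 = member).  Only non-empty patterns are returned; the
    pattern sets are disjoint and their union equals the union of the
    input lists.
    """
    if len(collection) < 2:
        raise ValueError("need at least two lists")
    names = list(collection)
    sets = {n: set(collection[n]) for n in names}
    universe = set().union(*sets.values())
    out: dict[tuple[int, ...], set[str]] = {}
    for gene in universe:
        pattern = tuple(int(gene in sets[n]) for n in names)
        out.setdefault(pattern, set()).add(gene)
    return out


def pattern_counts(
    collection: Mapping[str, Iterable[str]],
) -> dict[tuple[int, ...], int]:
    """Sizes of the non-empty membership patterns."""
    return {p: len(g) for p, g in membership_patterns(collection).items()}


def temporal_classes(
    de_early: Iterable[str],
    de_mid: Iterable[str],
    de_late: Iterable[str],
    reference_set: Iterable[str],
) -> dict[str, set[str]]:
    """Classify stage-wise DE genes by when they change.

    Within genes that are also in ``reference_set``: *early* = first
    stage only, *early-mid* = first and second but not third, *mid* =
    second only, *mid-later* = second and third but not first, *later* =
    third only, *persistent* = all three stages, *discontinuous* = first
    and third but not second.  Genes outside the reference set are
    returned under ``non-reference:<bit pattern>`` keys so the output
    still partitions the union of the three DE lists.
    """
    e, m, l = set(de_early), set(de_mid), set(de_late)
    ref = set(reference_set)
    union = e | m | l
    label_by_bits = {
        (1, 0, 0): "early",
        (1, 1, 0): "early-mid",
        (0, 1, 0): "mid",
        (0, 1, 1): "mid-later",
        (0, 0, 1): "later",
        (1, 1, 1): "persistent",
        (1, 0, 1): "discontinuous",
    }
    out: dict[str, set[str]] = {}
    for gene in union:
        bits = (int(gene in e), int(gene in m), int(gene in l))
        if gene in ref:
            key = label_by_bits[bits]
        else:
            key = "non-reference:" + "".join(map(str, bits))
        out.setdefault(key, set()).add(gene)
    return out
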