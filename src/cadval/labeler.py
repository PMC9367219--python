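"""Rule-based normal/abnormal labeling of radiology report descriptions.

A routine Vietnamese CXR report with no findings describes four fixed
anatomical regions — chest wall, pleura, lung, mediastinum — each with a
canonical sentence.  A region counts as normal iff one of its canonical
templates appears verbatim as a contiguous substring of the DESCRIPTION;
the report is normal iff all four regions are normal, otherwise abnormal.
The derived label serves as the ground truth the AI verdict is scored
against.

"Verbatim" needs an equality convention for free text: by default both the
templates and the description are normalized to Unicode NFC, case-folded,
and whitespace-collapsed before the substring test (diacritics preserved).
Raw matching without normalization is available via ``normalize=False``.
No sentence segmentation, negation handling, or fuzzy matching is applied;
the rule is deliberately minimal and is only meaningful for report corpora
that actually use the template sentences.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

#: The four thoracic regions, in canonical order.
REGIONS = ("chest_wall", "pleura", "lung", "mediastinum")

NORMAL = 0
ABNORMAL = 1


def normalize_text(text: str) -> str:
    """Canonicalize free text for verbatim comparison.

    Unicode NFC composition, case folding, runs of whitespace collapsed to a
    single space, and surrounding whitespace stripped.  Diacritics are
    preserved; the function is idempotent.
    """
    text = unicodedata.normalize("NFC", text)
    text = text.casefold()
    text = unicodedata.normalize("NFC", text)  # casefold can decompose
    return " ".join(text.split())


@dataclass(frozen=True)
class TemplateSet:
    """Per-region normal-description templates, stored pre-normalized."""

    region_templates: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.region_templates) != set(REGIONS):
            raise ValueError(
                f"template set must cover exactly the regions {REGIONS}, "
                f"got {sorted(self.region_templates)}"
            )
        for region, templates in self.region_templates.items():
            if not templates or any(not t for t in templates):
                raise ValueError(f"region {region!r} has an empty template")

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, Sequence[str]], normalize: bool = True
    ) -> "TemplateSet":
        return cls(
            region_templates={
                region: tuple(
                    normalize_text(t) if normalize else t for t in templates
                )
                for region, templates in mapping.items()
            }
        )

    @classmethod
    def load(cls, path: str | Path, normalize: bool = True) -> "TemplateSet":
        """Load a region -> list-of-strings template config (UTF-8 YAML)."""
        with open(path, encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh)
        return cls.from_mapping(mapping, normalize=normalize)

    @classmethod
    def default(cls) -> "TemplateSet":
        """The packaged Vietnamese template set."""
        ref = resources.files("cadval.data").joinpath("templates_vi.yaml")
        mapping = yaml.safe_load(ref.read_text(encoding="utf-8"))
        return cls.from_mapping(mapping)


@dataclass(frozen=True)
class ReportLabel:
    """Ground-truth verdict for one report: 0 normal, 1 abnormal."""

    label: int
    region_normal: Mapping[str, bool]


def region_is_normal(
    description: str, templates: Sequence[str], normalize: bool = True
) -> bool:
    """True iff one of the (pre-normalized) templates occurs as a contiguous
    substring of the description."""
    haystack = normalize_text(description) if normalize else description
    return any(t in haystack for t in templates)


def label_report(
    description: str, template_set: TemplateSet, normalize: bool = True
) -> ReportLabel:
    """Label a report description: normal iff all four regions are normal."""
    haystack = normalize_text(description) if normalize else description
    region_normal = {
        region: any(t in haystack for t in template_set.region_templates[region])
        for region in REGIONS
    }
    label = NORMAL if all(region_normal.values()) else ABNORMAL
    return ReportLabel(label=label, region_normal=region_normal)
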