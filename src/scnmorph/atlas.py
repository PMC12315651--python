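"""Desikan–Killiany cortical parcellation labels.

The 68 cortical regions of interest (34 per hemisphere) of the default
FreeSurfer ``aparc`` parcellation, in the canonical order used throughout the
package: left hemisphere first, regions in FreeSurfer's aparc table order.
All network matrices and cohort thickness columns are indexed in this order.
"""

from __future__ import annotations

# FreeSurfer aparc region names, one hemisphere (34 regions).
DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

HEMISPHERES: tuple[str, str] = ("lh", "rh")

#: Canonical 68 ROI labels (``lh_<region>``, then ``rh_<region>``).
DK_ROI_LABELS: tuple[str, ...] = tuple(
    f"{hemi}_{region}" for hemi in HEMISPHERES for region in DK_REGIONS
)

N_ROI: int = len(DK_ROI_LABELS)  # 68


def thickness_column(roi: str) -> str:
    """Column name used for a ROI's mean thickness in cohort tables."""
    return f"{roi}_thickness"


#: Thickness column names in canonical order, e.g. ``lh_fusiform_thickness``.
THICKNESS_COLUMNS: tuple[str, ...] = tuple(thickness_column(r) for r in DK_ROI_LABELS)


def validate_roi_labels(labels: list[str] | tuple[str, ...]) -> None:
    """Raise ``ValueError`` naming any label not in the atlas."""
    unknown = [lab for lab in labels if lab not in DK_ROI_LABELS]
    if unknown:
        raise ValueError(f"unknown ROI label(s): {unknown}")
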