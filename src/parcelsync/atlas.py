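"""Destrieux cortical parcellation labels and default region sets.

The Destrieux atlas (FreeSurfer ``aparc.a2009s``) divides each hemisphere
into 74 gyral/sulcal parcels, 148 bilaterally.  Labels here follow the
FreeSurfer naming with a ``-lh``/``-rh`` hemisphere suffix.

The default region sets are a documented stand-in: the study that motivated
this package restricted its inter-system analysis to the core system of the
face-processing network (fusiform, inferior/lateral occipital, superior
temporal sulcus) and to the primary and secondary motor and somatosensory
cortices, but published the exact parcel list only as supplementary
material.  The sets below cover those anatomical territories bilaterally
and can be overridden through any :class:`~parcelsync.network.ROISetPair`.
"""

from __future__ import annotations

_DESTRIEUX_BASE = (
    "G_and_S_frontomargin",
    "G_and_S_occipital_inf",
    "G_and_S_paracentral",
    "G_and_S_subcentral",
    "G_and_S_transv_frontopol",
    "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant",
    "G_and_S_cingul-Mid-Post",
    "G_cingul-Post-dorsal",
    "G_cingul-Post-ventral",
    "G_cuneus",
    "G_front_inf-Opercular",
    "G_front_inf-Orbital",
    "G_front_inf-Triangul",
    "G_front_middle",
    "G_front_sup",
    "G_Ins_lg_and_S_cent_ins",
    "G_insular_short",
    "G_occipital_middle",
    "G_occipital_sup",
    "G_oc-temp_lat-fusifor",
    "G_oc-temp_med-Lingual",
    "G_oc-temp_med-Parahip",
    "G_orbital",
    "G_pariet_inf-Angular",
    "G_pariet_inf-Supramar",
    "G_parietal_sup",
    "G_postcentral",
    "G_precentral",
    "G_precuneus",
    "G_rectus",
    "G_subcallosal",
    "G_temp_sup-G_T_transv",
    "G_temp_sup-Lateral",
    "G_temp_sup-Plan_polar",
    "G_temp_sup-Plan_tempo",
    "G_temporal_inf",
    "G_temporal_middle",
    "Lat_Fis-ant-Horizont",
    "Lat_Fis-ant-Vertical",
    "Lat_Fis-post",
    "Pole_occipital",
    "Pole_temporal",
    "S_calcarine",
    "S_central",
    "S_cingul-Marginalis",
    "S_circular_insula_ant",
    "S_circular_insula_inf",
    "S_circular_insula_sup",
    "S_collat_transv_ant",
    "S_collat_transv_post",
    "S_front_inf",
    "S_front_middle",
    "S_front_sup",
    "S_interm_prim-Jensen",
    "S_intrapariet_and_P_trans",
    "S_oc_middle_and_Lunatus",
    "S_oc_sup_and_transversal",
    "S_occipital_ant",
    "S_oc-temp_lat",
    "S_oc-temp_med_and_Lingual",
    "S_orbital_lateral",
    "S_orbital_med-olfact",
    "S_orbital-H_Shaped",
    "S_parieto_occipital",
    "S_pericallosal",
    "S_postcentral",
    "S_precentral-inf-part",
    "S_precentral-sup-part",
    "S_suborbital",
    "S_subparietal",
    "S_temporal_inf",
    "S_temporal_sup",
    "S_temporal_transverse",
)

#: All 148 Destrieux parcel labels, left hemisphere first.
DESTRIEUX_LABELS: tuple[str, ...] = tuple(
    f"{name}-{hemi}" for hemi in ("lh", "rh") for name in _DESTRIEUX_BASE
)

_SENSORIMOTOR_BASE = (
    "G_precentral",
    "G_postcentral",
    "G_and_S_paracentral",
    "G_and_S_subcentral",
    "S_central",
    "S_postcentral",
    "S_precentral-inf-part",
    "S_precentral-sup-part",
)

_CORE_BASE = (
    "G_oc-temp_lat-fusifor",
    "G_and_S_occipital_inf",
    "G_occipital_middle",
    "S_temporal_sup",
)

#: Primary/secondary motor and somatosensory parcels, bilateral (16 labels).
DEFAULT_SENSORIMOTOR: tuple[str, ...] = tuple(
    f"{name}-{hemi}" for hemi in ("lh", "rh") for name in _SENSORIMOTOR_BASE
)

#: Core face-processing system stand-in, bilateral (8 labels).
DEFAULT_CORE: tuple[str, ...] = tuple(
    f"{name}-{hemi}" for hemi in ("lh", "rh") for name in _CORE_BASE
)
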