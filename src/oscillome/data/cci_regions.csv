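acronym,full_name,exclusion_flag
AUDd,Dorsal auditory area,
CA3,"Hippocampus, field CA3",
DG,"Hippocampus, dentate gyrus",
PTLp,Posterior parietal association areas,voxel_count
RSPagl,"Retrosplenial area, lateral agranular part",voxel_count
RSPd,"Retrosplenial area, dorsal part",voxel_count
SSp-bfd,"Primary somatosensory area, barrel field",
SSp-tr,"Primary somatosensory area, trunk",
SSs,Supplemental somatosensory area,
VISal,Anterolateral visual area,voxel_count
VISam,Anteromedial visual area,voxel_count
VISl,Lateral visual area,signal_quality_subset
VISp,Primary visual area,
VISpm,Posteromedial visual area,
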