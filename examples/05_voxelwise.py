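"""Voxel-wise TFCE permutation mapping of lesion-atrophy coupling.

A small cohort is generated with extra ventricular dilation proportional to
each subject's TLVC; the full chain (TLVC estimation, edge displacement,
5-mm-sigma smoothed template maps, Freedman-Lane permutations with TFCE)
localises the coupling to the periventricular edge and reports it with the
>= 15-significant-voxel rule.
"""

import mslat.evaluation as ev

res = ev.voxelwise_localisation(n_subjects=20, n_perm=300, seed=7, target_t=4.0)
print(f"mean |t| in coupled region : {res['mean_abs_t_in_region']:.2f}")
print(f"significant voxels (FWE<.05): {res['n_significant']}")
print(f"sensitivity in coupled region: {100 * res['sensitivity']:.1f} %")
print(f"precision of significant set : {100 * res['precision']:.1f} %")
print("\nregion report (empty below 15 significant voxels):")
rep = res["report"]
print(rep.to_string(index=False) if len(rep) else "  (no reportable cluster)")
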