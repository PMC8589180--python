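"""Decompose traced combined regions and quantify overlap percentages.

The tracing protocol yields nested combined regions: A = attenuation +
IZ loss + EZ loss, B = IZ loss + EZ loss, C = EZ loss.  Subtraction gives
the exclusive classes, and each class's overlap with the telangiectasia
mask is expressed as a percent of the telangiectasia area.
"""

from izmap import SceneParams, area_mm2, decompose, generate_scene, percent_overlap

scene = generate_scene(SceneParams(stage_group="advanced", seed=19))
t = scene.truth
scale = scene.dcp.scale_mm_per_px

rs = decompose(t.region_combined_A, t.region_combined_B, t.region_ez_C, scale)
tel = t.telangiectasia

print("exclusive class areas (mm^2):")
print(f"  IZ attenuation only {area_mm2(rs.attn_only, scale):6.3f}")
print(f"  IZ loss only        {area_mm2(rs.izloss_only, scale):6.3f}")
print(f"  EZ loss             {area_mm2(rs.C, scale):6.3f}")
print("overlap with DCP telangiectasia (% of telangiectasia area):")
print(f"  IZ attenuation only {percent_overlap(tel, rs.attn_only):6.2f}")
print(f"  IZ loss only        {percent_overlap(tel, rs.izloss_only):6.2f}")
print(f"  EZ loss             {percent_overlap(tel, rs.C):6.2f}")
# In advanced disease most of the telangiectatic area overlies EZ loss;
# the three percentages never sum above 100 (the classes are disjoint).
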