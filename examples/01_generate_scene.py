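"""Generate one synthetic eye and report its ground-truth areas.

The scene bundles a superficial (SCP) and deep (DCP) capillary-plexus
angiogram, a photoreceptor-slab reflectance image, and ground-truth masks:
the telangiectatic zone, the SCP large vessels, and the nested
photoreceptor-disruption regions (attenuation ⊇ IZ loss ⊇ EZ loss).
"""

from izmap import SceneParams, area_mm2, generate_scene

scene = generate_scene(SceneParams(stage_group="advanced", seed=42))
t = scene.truth
scale = scene.dcp.scale_mm_per_px

print(f"field: {scene.dcp.shape[0]} px = {scene.dcp.field_mm} mm per side")
print(f"DCP telangiectasia     {area_mm2(t.telangiectasia, scale):6.3f} mm^2")
print(f"IZ attenuation (only)  {area_mm2(t.attn_only, scale):6.3f} mm^2")
print(f"IZ loss (only)         {area_mm2(t.izloss_only, scale):6.3f} mm^2")
print(f"EZ loss                {area_mm2(t.region_ez_C, scale):6.3f} mm^2")
print(f"SCP large vessels      {area_mm2(t.scp_large_vessels, scale):6.3f} mm^2")
# Areas are drawn per pooled disease group (early/moderate/advanced), so an
# advanced-stage eye carries large EZ loss and prominent telangiectasia.
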