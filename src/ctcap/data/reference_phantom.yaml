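# MIRD-style simplified hermaphrodite reference phantom.
#
# Coordinate system: z along the body axis with z = 0 at the trunk base
# (top of the legs); +y toward the anterior (front) surface; +x toward the
# phantom's left.  All lengths in cm.  Body regions are elliptical cylinders
# (half-axes a along x, b along y); organs are ellipsoids.  Regions not
# claimed by an organ are "rest of body" soft tissue.
reference:
  height_cm: 178.6
  weight_kg: 73.2

bodies:
  - {name: trunk, cx: 0.0, cy: 0.0, a: 20.0, b: 10.0, zmin: 0.0, zmax: 70.0, material: soft_tissue}
  - {name: head,  cx: 0.0, cy: 0.0, a: 7.0,  b: 10.0, zmin: 70.0, zmax: 94.0, material: soft_tissue}
  - {name: legs,  cx: 0.0, cy: 0.0, a: 14.9, b: 6.005, zmin: -84.6, zmax: 0.0, material: soft_tissue}

# Listed in scoring-priority order: where ellipsoids touch, the first entry
# in this list claims the point.  Names may repeat (multi-part organs).
organs:
  - {name: thyroid,               cx: 0.0,  cy: 4.0,  cz: 69.0, ax: 2.0,  ay: 1.5, az: 2.0,  material: soft_tissue}
  - {name: thymus,                cx: 0.0,  cy: 5.0,  cz: 62.0, ax: 2.5,  ay: 2.0, az: 3.0,  material: soft_tissue}
  - {name: esophagus,             cx: 0.0,  cy: -6.0, cz: 57.0, ax: 1.2,  ay: 1.2, az: 11.0, material: soft_tissue}
  - {name: eye,                   cx: 0.0,  cy: 8.5,  cz: 86.0, ax: 3.5,  ay: 1.2, az: 1.2,  material: soft_tissue}
  - {name: brain,                 cx: 0.0,  cy: 0.0,  cz: 84.0, ax: 6.0,  ay: 8.0, az: 7.0,  material: soft_tissue}
  - {name: adrenals_gall_bladder, cx: -5.0, cy: 5.0,  cz: 39.0, ax: 3.0,  ay: 2.5, az: 3.0,  material: soft_tissue}
  - {name: pancreas,              cx: -4.0, cy: 3.0,  cz: 37.0, ax: 6.0,  ay: 2.2, az: 2.0,  material: soft_tissue}
  - {name: kidney,                cx: 0.0,  cy: -5.0, cz: 36.0, ax: 9.0,  ay: 2.8, az: 5.5,  material: soft_tissue}
  - {name: liver,                 cx: 8.0,  cy: 1.0,  cz: 40.0, ax: 8.0,  ay: 7.0, az: 6.0,  material: soft_tissue}
  - {name: lung,                  cx: -8.0, cy: 0.0,  cz: 57.0, ax: 5.5,  ay: 7.0, az: 11.0, material: lung}
  - {name: lung,                  cx: 8.0,  cy: 0.0,  cz: 57.0, ax: 5.5,  ay: 7.0, az: 11.0, material: lung}
  - {name: colon,                 cx: 0.0,  cy: 2.0,  cz: 24.0, ax: 10.0, ay: 4.0, az: 8.0,  material: soft_tissue}
  - {name: uterus_testes,         cx: 0.0,  cy: 2.0,  cz: 12.0, ax: 2.5,  ay: 3.0, az: 4.0,  material: soft_tissue}
  - {name: uterus_testes,         cx: 0.0,  cy: 8.0,  cz: 3.0,  ax: 2.0,  ay: 1.5, az: 2.5,  material: soft_tissue}

materials:
  soft_tissue: {density_g_cm3: 1.04, table: water}
  lung:        {density_g_cm3: 0.26, table: water}
  bone:        {density_g_cm3: 1.92, table: bone_cortical}
  water:       {density_g_cm3: 1.00, table: water}
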