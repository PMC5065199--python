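"""Extract the 15 radiomic features from one synthetic tumor phantom.

Builds a lobulated ellipsoidal lesion (~20 mm) in lung-like background at
CT voxel spacing 0.68 x 0.68 x 1.00 mm, then extracts first-order intensity
features, mask-only shape features, and GLCM texture features.
"""

from ctradiomics import PhantomSpec, extract_features, generate_phantom

spec = PhantomSpec(grid_shape=(64, 64, 48), radii_mm=(10.0, 11.0, 9.0), seed=42)
volume, mask = generate_phantom(spec)

features = extract_features(volume, mask)
for name, value in features.as_dict().items():
    print(f"{name:22s} {value:12.4f}")

# mean/sd/skewness summarize the HU distribution inside the mask (skewness
# is negative: solid enhancing tumors have a long tail toward lung HU);
# volume is in mm^3, effective_diameter in mm, sphericity ~1 for round
# lesions; glcm_contrast/idm/entropy quantify local texture on 256 gray
# levels pooled over the 13 unique 3D directions.
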