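"""Generate one entropy-targeted synthetic IHC scene and inspect it.

Builds a 256x256 scene with microvessels, artery/vein and neuron
distractors on a background shaped to a 6.0-bit histogram entropy, then
prints the achieved entropy and the ground-truth structure inventory.
"""

from vesselseg.io import image_entropy
from vesselseg.structures import extract_structure_features
from vesselseg.synthesis import SceneParams, generate_scene

params = SceneParams(target_entropy_bits=6.0, seed=42)
scene = generate_scene(params)

print(f"target entropy : {params.target_entropy_bits:.2f} bits")
print(f"achieved       : {scene.achieved_entropy_bits:.3f} bits "
      "(256-bin gray-level histogram)")
print(f"re-measured    : {image_entropy(scene.image):.3f} bits")
print(f"structures     : {scene.truth_labelmap.n_structures}")

records = extract_structure_features(scene.truth_labelmap, scene.image)
print(f"{'id':>3} {'class':<12} {'area':>6} {'aspect':>7} {'solidity':>9}")
for rec, cls in zip(records, scene.truth_classes):
    print(f"{rec.structure_id:>3} {cls:<12} {rec.area_px:>6} "
          f"{rec.aspect_ratio:>7.2f} {rec.solidity:>9.2f}")

# Microvessels are elongated (high aspect), arteries are wide tubes with
# much larger area, neurons are compact blobs with lower solidity; these
# geometric contrasts are what the decision forest learns to separate.
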