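"""ROI imaging formulas: SNR, CNR and caliper tumor volume.

SNR = 0.655 x (tumor-ROI mean / average of background-ROI means);
CNR = SNR_pre − SNR_post (sign as printed, magnitude also reported);
V = (length/2) x width^2 for caliper measurements in mm.
"""

from wulffgraft.analysis import cnr, snr, tumor_volume
from wulffgraft.fixtures import synth_roi_image

# equal tumor/background means -> SNR equals the formula constant
img, tumor, bgs, _ = synth_roi_image(tumor_mean=100, background_mean=100)
res_pre = snr(img, tumor, bgs)
print(f"equal-means image : SNR = {res_pre.snr:.3f} "
      "(= 0.655, the formula constant)")

# twice the background intensity in the tumor ROI
img2, tumor2, bgs2, _ = synth_roi_image(tumor_mean=131, background_mean=65.5)
res_post = snr(img2, tumor2, bgs2)
print(f"2x contrast image : SNR = {res_post.snr:.3f} (= 0.655 x 2)")

c = cnr(res_pre.snr, res_post.snr)
print(f"CNR(pre, post)    : {c['cnr']:.3f} (magnitude {c['magnitude']:.3f})")

for length, width in [(2.0, 1.0), (10.0, 4.0), (8.4, 6.1)]:
    v = tumor_volume(length, width)
    print(f"tumor {length:4.1f} x {width:3.1f} mm -> V = {v:7.2f} mm^3")
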