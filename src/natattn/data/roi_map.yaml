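# Default channel -> region-of-interest map (0-based channel indices).
# Six bilateral ROIs: medial frontal gyrus (2 channels each), superior
# temporal sulcus/gyrus (6 each), temporo-parietal junction (3 each:
# two angular-gyrus channels and one supramarginal channel).
# The layout is an illustrative fixture: real ROI membership comes from an
# infant channel-localization atlas and is supplied by the user as config.
lMFG: [0, 1]
rMFG: [22, 23]
lSTS: [4, 5, 6, 7, 8, 9]
rSTS: [26, 27, 28, 29, 30, 31]
lTPJ: [10, 11, 12]
rTPJ: [32, 33, 34]
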