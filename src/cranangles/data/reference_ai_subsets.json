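{
 "version": 1,
 "note": "Reference attribute-importance subsets from the source study's reported selection run; shipped for comparison only, never used by the selection algorithm.",
 "subsets": {
  ">0": [
   "n-m-FH",
   "n-g-m",
   "ob-l-FH",
   "l-op-FH",
   "op-i-FH",
   "l-op-i",
   "ba-o-FH",
   "n-i-FH",
   "po-ms-ast (L)",
   "n-pr-ba",
   "fmo-n-fmo",
   "zm-ss-zm",
   "g-n-rhi",
   "zm-zo-FH (L)",
   "so-zo-FH (R)",
   "so-zo-FH (L)",
   "n-mn-rhi",
   "nm-rhi-nm",
   "nl-ss-nl"
  ],
  ">=0.1": [
   "n-m-FH",
   "n-g-m",
   "ob-l-FH",
   "op-i-FH",
   "po-ms-ast (L)",
   "fmo-n-fmo",
   "zm-ss-zm",
   "g-n-rhi",
   "zm-zo-FH (L)",
   "so-zo-FH (R)",
   "so-zo-FH (L)",
   "n-mn-rhi",
   "nm-rhi-nm",
   "nl-ss-nl"
  ],
  ">=0.3": [
   "n-m-FH",
   "n-g-m",
   "ob-l-FH",
   "op-i-FH",
   "po-ms-ast (L)",
   "fmo-n-fmo",
   "g-n-rhi",
   "zm-zo-FH (L)",
   "so-zo-FH (R)",
   "n-mn-rhi",
   "nm-rhi-nm",
   "nl-ss-nl"
  ],
  ">=0.4": [
   "n-m-FH",
   "n-g-m",
   "ob-l-FH",
   "op-i-FH",
   "fmo-n-fmo",
   "g-n-rhi",
   "n-mn-rhi",
   "nm-rhi-nm",
   "nl-ss-nl"
  ],
  ">=0.6": [
   "n-m-FH",
   "n-g-m",
   "op-i-FH",
   "fmo-n-fmo",
   "g-n-rhi",
   "nm-rhi-nm",
   "nl-ss-nl"
  ],
  ">=0.9": [
   "n-m-FH",
   "n-g-m",
   "op-i-FH",
   "fmo-n-fmo",
   "g-n-rhi",
   "nm-rhi-nm"
  ],
  "=1": [
   "n-m-FH",
   "n-g-m",
   "fmo-n-fmo",
   "nm-rhi-nm"
  ]
 }
}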