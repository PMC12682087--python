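{
  "scale": {
    "1": "Strongly disagree",
    "2": "Disagree",
    "3": "Neutral",
    "4": "Agree",
    "5": "Strongly agree"
  },
  "descriptors": [
    "There are arcs or curves.",
    "There are features that resemble wheel spokes (e.g., lines radiating from the centre).",
    "There are distinct bands or lines.",
    "There are multiple spokes or tails emanating from the central section of this image.",
    "There is a single quadrant/section with lines or spokes.",
    "There are multiple quadrants/sections with lines or spokes.",
    "There is a central core.",
    "A central core makes up most of the image.",
    "If you divide the image vertically, the left side looks like the right.",
    "If you divide the image horizontally, the top looks like the bottom.",
    "There is complexity. For this question, a simple image would have a few distinct features, and a complex image has many distinct features.",
    "There is regularity. For this question, 'regular' means there is a consistent and predictable pattern of elements (e.g., a spiral), versus 'irregular' (e.g., a splat of paint).",
    "The brightness or density is uniform throughout the image."
  ]
}
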