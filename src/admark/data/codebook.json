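{
  "appeal_types": {
    "senses": {
      "strategy": "emotional",
      "definition": "PLACEHOLDER - replace with the project codebook text. References or depictions of taste, smell, texture, sound or visual pleasure associated with consuming the product."
    },
    "cartoons": {
      "strategy": "emotional",
      "definition": "PLACEHOLDER - replace with the project codebook text. Cartoon characters, animated animals or other animations used to present the product."
    },
    "positive_emotions": {
      "strategy": "emotional",
      "definition": "PLACEHOLDER - replace with the project codebook text. Associations between the product and fun, happiness, excitement or other positive emotional states."
    },
    "characters": {
      "strategy": "emotional",
      "definition": "PLACEHOLDER - replace with the project codebook text. Licensed characters, brand mascots, celebrities or child actors modelling consumption."
    },
    "fun_adventure": {
      "strategy": "emotional",
      "definition": "PLACEHOLDER - replace with the project codebook text. Imagination, adventure, play or fantasy scenarios built around the product."
    },
    "health": {
      "strategy": "rational",
      "definition": "PLACEHOLDER - replace with the project codebook text. Claims about health advantages or benefits of consuming the product."
    },
    "nutrition": {
      "strategy": "rational",
      "definition": "PLACEHOLDER - replace with the project codebook text. Claims about nutrient content or nutritional advantages of the product."
    },
    "freshness": {
      "strategy": "rational",
      "definition": "PLACEHOLDER - replace with the project codebook text. Claims that the product or its components are fresh or natural."
    },
    "ingredients": {
      "strategy": "rational",
      "definition": "PLACEHOLDER - replace with the project codebook text. Statements describing the ingredients or composition of the product."
    },
    "quality": {
      "strategy": "rational",
      "definition": "PLACEHOLDER - replace with the project codebook text. Claims about the quality, premium character or careful production of the product."
    }
  }
}
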