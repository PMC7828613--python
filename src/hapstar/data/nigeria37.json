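{
  "comment": "Hand-encoded approximate contiguity for Nigeria's 36 states plus the Federal Capital Territory, grouped into the six geopolitical regions. An encoding choice for testing spatial models, not survey-grade GIS contiguity.",
  "area_labels": [
    "Abia", "Adamawa", "Akwa Ibom", "Anambra", "Bauchi", "Bayelsa", "Benue",
    "Borno", "Cross River", "Delta", "Ebonyi", "Edo", "Ekiti", "Enugu",
    "FCT Abuja", "Gombe", "Imo", "Jigawa", "Kaduna", "Kano", "Katsina",
    "Kebbi", "Kogi", "Kwara", "Lagos", "Nasarawa", "Niger", "Ogun", "Ondo",
    "Osun", "Oyo", "Plateau", "Rivers", "Sokoto", "Taraba", "Yobe", "Zamfara"
  ],
  "region_labels": [
    "North-Central", "North-East", "North-West",
    "South-East", "South-South", "South-West"
  ],
  "region_of_area": {
    "Abia": "South-East", "Adamawa": "North-East", "Akwa Ibom": "South-South",
    "Anambra": "South-East", "Bauchi": "North-East", "Bayelsa": "South-South",
    "Benue": "North-Central", "Borno": "North-East", "Cross River": "South-South",
    "Delta": "South-South", "Ebonyi": "South-East", "Edo": "South-South",
    "Ekiti": "South-West", "Enugu": "South-East", "FCT Abuja": "North-Central",
    "Gombe": "North-East", "Imo": "South-East", "Jigawa": "North-West",
    "Kaduna": "North-West", "Kano": "North-West", "Katsina": "North-West",
    "Kebbi": "North-West", "Kogi": "North-Central", "Kwara": "North-Central",
    "Lagos": "South-West", "Nasarawa": "North-Central", "Niger": "North-Central",
    "Ogun": "South-West", "Ondo": "South-West", "Osun": "South-West",
    "Oyo": "South-West", "Plateau": "North-Central", "Rivers": "South-South",
    "Sokoto": "North-West", "Taraba": "North-East", "Yobe": "North-East",
    "Zamfara": "North-West"
  },
  "edges": [
    ["Sokoto", "Kebbi"], ["Sokoto", "Zamfara"],
    ["Kebbi", "Zamfara"], ["Kebbi", "Niger"],
    ["Zamfara", "Katsina"], ["Zamfara", "Kaduna"], ["Zamfara", "Niger"],
    ["Katsina", "Kaduna"], ["Katsina", "Kano"], ["Katsina", "Jigawa"],
    ["Kano", "Jigawa"], ["Kano", "Kaduna"], ["Kano", "Bauchi"],
    ["Jigawa", "Bauchi"], ["Jigawa", "Yobe"],
    ["Yobe", "Bauchi"], ["Yobe", "Gombe"], ["Yobe", "Borno"],
    ["Borno", "Gombe"], ["Borno", "Adamawa"],
    ["Adamawa", "Gombe"], ["Adamawa", "Taraba"],
    ["Gombe", "Bauchi"], ["Gombe", "Taraba"],
    ["Bauchi", "Taraba"], ["Bauchi", "Plateau"], ["Bauchi", "Kaduna"],
    ["Taraba", "Plateau"], ["Taraba", "Benue"], ["Taraba", "Nasarawa"],
    ["Plateau", "Kaduna"], ["Plateau", "Nasarawa"],
    ["Kaduna", "Niger"], ["Kaduna", "Nasarawa"], ["Kaduna", "FCT Abuja"],
    ["Niger", "FCT Abuja"], ["Niger", "Kogi"], ["Niger", "Kwara"],
    ["FCT Abuja", "Nasarawa"], ["FCT Abuja", "Kogi"],
    ["Nasarawa", "Benue"], ["Nasarawa", "Kogi"],
    ["Benue", "Kogi"], ["Benue", "Enugu"], ["Benue", "Ebonyi"],
    ["Benue", "Cross River"],
    ["Kogi", "Kwara"], ["Kogi", "Ekiti"], ["Kogi", "Ondo"], ["Kogi", "Edo"],
    ["Kogi", "Anambra"], ["Kogi", "Enugu"],
    ["Kwara", "Oyo"], ["Kwara", "Osun"], ["Kwara", "Ekiti"],
    ["Oyo", "Ogun"], ["Oyo", "Osun"],
    ["Osun", "Ogun"], ["Osun", "Ondo"], ["Osun", "Ekiti"],
    ["Ekiti", "Ondo"],
    ["Ondo", "Ogun"], ["Ondo", "Edo"], ["Ondo", "Delta"],
    ["Ogun", "Lagos"],
    ["Edo", "Delta"], ["Edo", "Anambra"],
    ["Delta", "Anambra"], ["Delta", "Imo"], ["Delta", "Rivers"],
    ["Delta", "Bayelsa"],
    ["Anambra", "Enugu"], ["Anambra", "Imo"],
    ["Enugu", "Ebonyi"], ["Enugu", "Abia"],
    ["Ebonyi", "Abia"], ["Ebonyi", "Cross River"],
    ["Abia", "Imo"], ["Abia", "Rivers"], ["Abia", "Akwa Ibom"],
    ["Abia", "Cross River"],
    ["Imo", "Rivers"],
    ["Rivers", "Bayelsa"], ["Rivers", "Akwa Ibom"],
    ["Akwa Ibom", "Cross River"]
  ]
}
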