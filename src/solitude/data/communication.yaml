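# Communication-phrase lexicon: approximate contacts-per-month for frequency
# phrases, and communication mode for mode phrases.  Editable configuration.
frequency:
  every day: 30
  most days: 20
  several times a week: 13
  twice a week: 8.66
  once a week: 4.33
  every week: 4.33
  couple times a month: 2
  twice a month: 2
  once a month: 1
  every month: 1
mode:
  phone: phone
  call: phone
  telephone: phone
  email: email
  e-mail: email
  facebook: social_media
  instagram: social_media
  social media: social_media
  in person: in_person
  visit: in_person
  video: video
  zoom: video
  skype: video
  facetime: video
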